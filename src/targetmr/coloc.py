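"""Bayesian colocalization of exposure and outcome association signals.

Under the single-causal-variant assumption, the evidence that a region's
exposure and outcome signals share one causal variant is summarized by five
posterior probabilities:

* PP0 — no association with either trait
* PP1 — association with the exposure only
* PP2 — association with the outcome only
* PP3 — both traits associated, distinct causal variants
* PP4 — both traits associated, one shared causal variant

Per-variant evidence enters through Wakefield's log approximate Bayes factor
(ABF); hypothesis sums are prior-weighted and accumulated in log space. A
PP4 strictly above 0.8 is taken as sufficient evidence of colocalization.

Regions with several exposure signals are first decomposed by a COJO-style
stepwise conditional analysis on summary statistics with a reference LD
matrix; each signal is then colocalized separately on statistics conditioned
on the other leads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp

from .errors import AlignmentError, CollinearityError
from .sumstats import LDMatrix, SumStats, VariantKey

logger = logging.getLogger(__name__)

#: default prior effect SDs for the ABF: per-SD quantitative traits and
#: log-odds binary traits (the conventional coloc defaults)
W_QUANTITATIVE = 0.15
W_BINARY = 0.2


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of association."""

    p1: float = 1e-4   # exposure only
    p2: float = 1e-4   # outcome only
    p12: float = 1e-5  # shared causal variant

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum below 1")


@dataclass
class ColocResult:
    pp: np.ndarray                 # PP0..PP4
    n_variants: int
    priors: ColocPriors
    lead: VariantKey | None = None
    signal_index: int = 0

    def __post_init__(self):
        self.pp = np.asarray(self.pp, float)
        if self.pp.shape != (5,):
            raise ValueError("expected five posterior probabilities")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posteriors do not sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def colocalized(self, pp4_min: float = 0.8) -> bool:
        """Strict inequality: PP4 must exceed the threshold."""
        return self.pp4 > pp4_min


@dataclass
class ConditionalSignal:
    """One conditionally independent association signal in a region."""

    lead: VariantKey
    variants: list[VariantKey]
    conditional_beta: np.ndarray
    conditional_se: np.ndarray
    conditional_p: np.ndarray


def labf(beta, se, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association.

    With V = se^2, r = W^2/(W^2 + V) and z = beta/se:
    labf = 0.5 * (log(1 - r) + r z^2).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("labf requires se > 0")
    if prior_sd <= 0:
        raise ValueError("labf requires a positive prior SD")
    V = se ** 2
    r = prior_sd ** 2 / (prior_sd ** 2 + V)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when equal (or b overtakes by rounding)."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_pp(labf_x: np.ndarray, labf_y: np.ndarray,
             priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Posterior probabilities PP0..PP4 from aligned per-variant log-ABFs.

    Hypothesis sums (log space, log-sum-exp throughout):
    H1 = p1 * sum_i ABF_x[i];  H2 = p2 * sum_i ABF_y[i];
    H3 = p1 p2 * (sum_i ABF_x sum_j ABF_y - sum_i ABF_x ABF_y)  (i != j);
    H4 = p12 * sum_i ABF_x[i] ABF_y[i];  H0 = 1.
    """
    lx = np.asarray(labf_x, float)
    ly = np.asarray(labf_y, float)
    if lx.shape != ly.shape or lx.ndim != 1 or lx.size == 0:
        raise AlignmentError("labf vectors must be 1-D, non-empty, and aligned")

    lsx = float(logsumexp(lx))
    lsy = float(logsumexp(ly))
    lsxy = float(logsumexp(lx + ly))
    lh3_sum = _logdiffexp(lsx + lsy, lsxy)  # cross terms only; -inf for n = 1

    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    lh = np.array([0.0, lp1 + lsx, lp2 + lsy, lp1 + lp2 + lh3_sum, lp12 + lsxy])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=lx.size, priors=priors)


def _conditional_stats(z: np.ndarray, se: np.ndarray, R: np.ndarray,
                       cond_idx: Sequence[int]):
    """Conditional summary statistics given a conditioning set of variants.

    Works on z-scores with the reference LD matrix: for conditioning set C,
    z_C^joint = R_CC^-1 z_C, and for each other variant v

        num_v = z_v - R_vC R_CC^-1 z_C,   d_v = 1 - R_vC R_CC^-1 R_Cv,
        beta_cond = se_v * num_v / d_v,   se_cond = se_v / sqrt(d_v),

    i.e. the candidate's coefficient in a joint model over C + {v}. Variants
    nearly collinear with C (d < 1e-6) get NaN conditional statistics.
    Empty conditioning set returns the marginal statistics.
    """
    n = len(z)
    if len(cond_idx) == 0:
        return se * z, se.copy(), 2 * stats.norm.sf(np.abs(z))
    C = np.asarray(cond_idx, int)
    Rcc = R[np.ix_(C, C)]
    try:
        Rcc_inv = linalg.inv(Rcc + np.eye(len(C)) * 1e-10)
    except linalg.LinAlgError:
        raise CollinearityError("singular joint system in conditional analysis")
    Rvc = R[:, C]                      # n x |C|
    b = Rcc_inv @ z[C]
    num = z - Rvc @ b
    d = 1.0 - np.einsum("ij,jk,ik->i", Rvc, Rcc_inv, Rvc)
    bad = d < 1e-6
    d_safe = np.where(bad, np.nan, d)
    beta_cond = se * num / d_safe
    se_cond = se / np.sqrt(d_safe)
    z_cond = num / np.sqrt(d_safe)
    p_cond = 2 * stats.norm.sf(np.abs(z_cond))
    return beta_cond, se_cond, p_cond


def stepwise_conditional(region: SumStats, ld: LDMatrix, p_entry: float = 5e-8,
                         r2_collinear: float = 0.9,
                         max_signals: int = 10) -> list[ConditionalSignal]:
    """COJO-style stepwise decomposition of a region into independent signals.

    Iteratively adds the variant with the smallest conditional p-value below
    ``p_entry``, skipping candidates with r^2 > ``r2_collinear`` against any
    selected lead. Conditional effects come from a joint GLS on z-scores with
    the reference LD (a summary-statistic simplification of COJO without
    per-variant sample-size adjustment).

    Each returned signal reports conditional statistics for all region
    variants conditioned on the *other* leads.
    """
    t = region.table
    if t.empty:
        return []
    keys = region.keys()
    order = {v.ident: i for i, v in enumerate(ld.variants)}
    try:
        idx = [order[k.ident] for k in keys]
    except KeyError as e:
        raise AlignmentError(f"region variant missing from LD matrix: {e}")
    R = ld.r[np.ix_(idx, idx)]
    beta = t["beta"].to_numpy(float)
    se = t["se"].to_numpy(float)
    z = beta / se
    n = len(z)
    r2 = R ** 2

    selected: list[int] = []
    while len(selected) < max_signals:
        _, _, p_cond = _conditional_stats(z, se, R, selected)
        cand_mask = np.ones(n, bool)
        cand_mask[selected] = False
        for s in selected:
            cand_mask &= ~(r2[:, s] > r2_collinear)
        cand_mask &= np.isfinite(p_cond)
        if not cand_mask.any():
            break
        cand = np.flatnonzero(cand_mask)
        best = cand[np.argmin(p_cond[cand])]
        if p_cond[best] >= p_entry:
            break
        selected.append(int(best))

    signals = []
    for lead in selected:
        others = [s for s in selected if s != lead]
        b_c, s_c, p_c = _conditional_stats(z, se, R, others)
        keep = [i for i in range(n) if i not in others and np.isfinite(s_c[i])]
        signals.append(ConditionalSignal(
            lead=keys[lead],
            variants=[keys[i] for i in keep],
            conditional_beta=b_c[keep],
            conditional_se=s_c[keep],
            conditional_p=p_c[keep],
        ))
    return signals


def colocalize_region(exposure_region: SumStats, outcome_region: SumStats,
                      ld: LDMatrix, priors: ColocPriors = ColocPriors(),
                      pp4_min: float = 0.8, maf_min: float = 0.01,
                      p_entry: float = 5e-8,
                      w_exposure: float = W_QUANTITATIVE,
                      w_outcome: float | None = None) -> list[ColocResult]:
    """Colocalize one gene region's exposure and outcome signals.

    Variants are intersected by identity after a MAF > ``maf_min`` filter in
    both datasets. The exposure region is decomposed by stepwise conditional
    analysis; each signal is colocalized against the outcome with both traits'
    statistics conditioned on the other exposure leads (marginal statistics
    when there is a single or no formal signal).
    """
    if w_outcome is None:
        w_outcome = W_BINARY if outcome_region.trait_type == "binary" else W_QUANTITATIVE

    def _flt(s: SumStats) -> pd.DataFrame:
        t = s.table
        maf = np.minimum(t["eaf"], 1 - t["eaf"])
        return t[maf > maf_min]

    ex, oy = _flt(exposure_region), _flt(outcome_region)
    ex_ids = {f"{r.chrom}:{r.pos}:{r.effect_allele}:{r.other_allele}" for r in ex.itertuples()}

    def _ident(df):
        return (df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":"
                + df["effect_allele"] + ":" + df["other_allele"])

    oy_idx = _ident(oy)
    shared = [i for i, ident in zip(oy.index, oy_idx) if ident in ex_ids]
    if not shared:
        raise AlignmentError("exposure and outcome regions share no variants after MAF filter")
    oy = oy.loc[shared]
    shared_ids = set(_ident(oy))
    ex = ex[_ident(ex).isin(shared_ids)]
    ex = ex.sort_values(["chrom", "pos", "effect_allele"]).reset_index(drop=True)
    oy = oy.sort_values(["chrom", "pos", "effect_allele"]).reset_index(drop=True)

    ex_s = SumStats(exposure_region.trait, exposure_region.trait_type, ex)
    oy_s = SumStats(outcome_region.trait, outcome_region.trait_type, oy)
    keys = ex_s.keys()
    lds = ld.subset(keys)

    signals = stepwise_conditional(ex_s, lds, p_entry=p_entry)
    results: list[ColocResult] = []
    if len(signals) <= 1:
        lx = labf(ex["beta"].to_numpy(), ex["se"].to_numpy(), w_exposure)
        ly = labf(oy["beta"].to_numpy(), oy["se"].to_numpy(), w_outcome)
        res = coloc_pp(lx, ly, priors)
        res.lead = signals[0].lead if signals else None
        results.append(res)
        return results

    order = {k.ident: i for i, k in enumerate(keys)}
    zy = oy["beta"].to_numpy() / oy["se"].to_numpy()
    sy = oy["se"].to_numpy()
    lead_idx = [order[s.lead.ident] for s in signals]
    for si, sig in enumerate(signals):
        others = [l for l in lead_idx if l != order[sig.lead.ident]]
        kept = [order[v.ident] for v in sig.variants]
        by_c, sy_c, _ = _conditional_stats(zy, sy, lds.r, others)
        ok = [j for j, i in enumerate(kept) if np.isfinite(sy_c[i])]
        kept_ok = [kept[j] for j in ok]
        lx = labf(sig.conditional_beta[ok], sig.conditional_se[ok], w_exposure)
        ly = labf(by_c[kept_ok], sy_c[kept_ok], w_outcome)
        res = coloc_pp(lx, ly, priors)
        res.lead = sig.lead
        res.signal_index = si
        results.append(res)
    return results
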