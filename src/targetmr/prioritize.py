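"""Drug-target prioritization: therapeutic orientation, replication
concordance, p-value distribution checks, OR quartile summaries, drug
annotation matching, and a region-based phenome-wide scan.

Estimates arrive on the per-SD-increase scale of each lipid. The therapeutic
direction recodes them toward the intended pharmacological perturbation —
lower LDL-C, lower triglycerides, higher HDL-C — so ``therapeutic_or < 1``
always reads "beneficial for disease risk".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InsufficientSampleError
from .instruments import GeneRegion
from .mr import MREstimate
from .sumstats import COMPLEMENT, SumStats

#: lipids whose therapeutic direction is a *decrease*
LOWERING_LIPIDS = {"LDL-C", "TG"}
RAISING_LIPIDS = {"HDL-C"}

DEFAULT_KEYWORDS = ["lipo", "lipid", "ldl", "hdl", "cholest", "triglyceride"]


@dataclass
class OrientedEstimate:
    """An MR estimate recoded toward the canonical drug-target direction."""

    base: MREstimate
    lipid: str
    therapeutic_or: float
    ci_low: float
    ci_high: float
    beneficial: bool
    significant: bool

    @property
    def unit(self) -> str:
        return self.base.unit


@dataclass
class ConcordanceReport:
    n_discovery_significant: int
    n_replication_tested: int
    n_replication_significant: int
    n_concordant: int
    fraction_concordant: float
    rows: pd.DataFrame


@dataclass(frozen=True)
class AnnotationMatch:
    gene: str
    source: str
    category: str
    matched_text: str
    keyword: str


def orient(estimate: MREstimate, lipid: str, alpha: float = 0.05) -> OrientedEstimate:
    """Recode an OR (per SD *increase* in the lipid) to the therapeutic direction.

    LDL-C and TG targets act by lowering, so their OR is inverted (CI bounds
    swap); HDL-C targets act by raising, so the OR passes through unchanged.
    """
    or_, (lo, hi) = estimate.or_, estimate.or_ci
    if lipid in LOWERING_LIPIDS:
        t_or, t_lo, t_hi = 1.0 / or_, 1.0 / hi, 1.0 / lo
    elif lipid in RAISING_LIPIDS:
        t_or, t_lo, t_hi = or_, lo, hi
    else:
        raise ValueError(f"unknown lipid '{lipid}' (expected LDL-C, HDL-C, or TG)")
    return OrientedEstimate(
        base=estimate, lipid=lipid, therapeutic_or=t_or, ci_low=t_lo, ci_high=t_hi,
        beneficial=t_or < 1.0, significant=estimate.pvalue < alpha,
    )


def ks_uniformity(pvalues: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample KS test of p-values against Uniform(0, 1).

    Used to check whether a batch of discovery p-values departs from the
    uniform distribution expected under the global null.
    """
    p = np.asarray(pvalues, float)
    if p.size < 5:
        raise InsufficientSampleError(f"KS uniformity check needs >= 5 p-values, got {p.size}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def replication_concordance(discovery: Sequence[OrientedEstimate],
                            replication: Sequence[OrientedEstimate],
                            alpha: float = 0.05) -> ConcordanceReport:
    """Directional concordance of replication-significant estimates.

    Units are matched by (gene, lipid). Among replication estimates with
    p < ``alpha``, an estimate is concordant when its therapeutic OR falls on
    the same side of 1 as the discovery estimate. The reported fraction is
    n_concordant / n_replication_significant.
    """
    disc = {(e.unit, e.lipid): e for e in discovery}
    overlap = [(e, disc[(e.unit, e.lipid)]) for e in replication
               if (e.unit, e.lipid) in disc]
    if not overlap:
        raise AlignmentError("no overlapping (gene, lipid) units between discovery and replication")

    rows = []
    n_sig = n_conc = 0
    for rep, d in overlap:
        sig = rep.base.pvalue < alpha
        conc = (rep.therapeutic_or < 1) == (d.therapeutic_or < 1)
        if sig:
            n_sig += 1
            n_conc += int(conc)
        rows.append({
            "unit": rep.unit, "lipid": rep.lipid,
            "discovery_or": d.therapeutic_or, "discovery_p": d.base.pvalue,
            "replication_or": rep.therapeutic_or, "replication_p": rep.base.pvalue,
            "replication_significant": sig, "concordant": conc,
        })
    return ConcordanceReport(
        n_discovery_significant=sum(e.significant for e in discovery),
        n_replication_tested=len(overlap),
        n_replication_significant=n_sig,
        n_concordant=n_conc,
        fraction_concordant=(n_conc / n_sig) if n_sig else float("nan"),
        rows=pd.DataFrame(rows),
    )


def summarize_quartiles(oriented: Sequence[OrientedEstimate],
                        min_group: int = 4) -> pd.DataFrame:
    """Q1/Q3 of significant per-SD-increase ORs, per lipid.

    ORs are taken on the per-SD-increase scale (the raw estimate, before
    therapeutic recoding). Quantiles use linear interpolation between order
    statistics. Lipid groups with fewer than ``min_group`` significant
    estimates are skipped.
    """
    rows = []
    for lipid in sorted({e.lipid for e in oriented}):
        ors = [e.base.or_ for e in oriented if e.lipid == lipid and e.significant]
        if len(ors) < min_group:
            continue
        q1, q3 = np.quantile(ors, [0.25, 0.75])  # linear interpolation default
        rows.append({"lipid": lipid, "n_significant": len(ors),
                     "q1_or": float(q1), "q3_or": float(q3)})
    return pd.DataFrame(rows, columns=["lipid", "n_significant", "q1_or", "q3_or"])


def match_annotations(genes: Sequence[str], records: pd.DataFrame,
                      keywords: Sequence[str] = DEFAULT_KEYWORDS,
                      mode: Literal["substring", "token_prefix"] = "substring",
                      ) -> list[AnnotationMatch]:
    """Keyword-stem matching of drug-annotation free text.

    ``records`` columns: gene, source, category, text, and (optionally)
    affected — adverse-event records with affected == 0 are excluded. Stems
    match case-insensitively, either anywhere in the text (``substring``,
    default: catches "hyperlipidaemia" under "lipid") or as prefixes of
    whitespace/punctuation-delimited tokens (``token_prefix``).
    One match is emitted per (gene, record, keyword).
    """
    gene_set = set(genes)
    out: list[AnnotationMatch] = []
    has_affected = "affected" in records.columns
    for r in records.itertuples():
        if r.gene not in gene_set:
            continue
        if has_affected and r.category == "adverse event":
            affected = getattr(r, "affected")
            if pd.notna(affected) and float(affected) < 1:
                continue
        text = str(r.text)
        low = text.lower()
        tokens = re.split(r"[^a-z0-9]+", low) if mode == "token_prefix" else None
        for kw in keywords:
            k = kw.lower().rstrip("*")
            hit = (k in low) if mode == "substring" else any(t.startswith(k) for t in tokens)
            if hit:
                out.append(AnnotationMatch(gene=r.gene, source=str(r.source),
                                           category=str(r.category),
                                           matched_text=text, keyword=kw))
    return out


def phewas_scan(genes: Sequence[GeneRegion], phenotypes: Sequence[SumStats],
                flank: int = 50_000, p_gw: float = 5e-8,
                palindrome_maf: float = 0.3) -> pd.DataFrame:
    """Region-based phenome-wide scan.

    For each gene x phenotype, reports the minimum association p-value among
    variants within [start - flank, end + flank] (inclusive), after removing
    palindromic variants with MAF >= ``palindrome_maf`` (strand unresolvable).
    Flags cells with min-p < ``p_gw``. Phenotypes with no region variants are
    recorded with NaN min-p and flag False.
    """
    rows = []
    for gene in genes:
        lo = max(1, gene.start - flank)
        hi = gene.end + flank
        for pheno in phenotypes:
            t = pheno.table
            sub = t[(t["chrom"].astype(str) == str(gene.chrom))
                    & (t["pos"] >= lo) & (t["pos"] <= hi)]
            if not sub.empty:
                pal = sub.apply(
                    lambda r: COMPLEMENT.get(r["effect_allele"]) == r["other_allele"], axis=1)
                maf = np.minimum(sub["eaf"], 1 - sub["eaf"])
                sub = sub[~(pal & (maf >= palindrome_maf))]
            if sub.empty:
                rows.append({"gene": gene.symbol, "phenotype": pheno.trait,
                             "n_variants": 0, "min_p": np.nan, "genomewide_significant": False})
                continue
            min_p = float(sub["pvalue"].min())
            rows.append({"gene": gene.symbol, "phenotype": pheno.trait,
                         "n_variants": int(len(sub)), "min_p": min_p,
                         "genomewide_significant": bool(min_p < p_gw)})
    return pd.DataFrame(rows)
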