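"""Synthetic GWAS data with known causal architecture.

Everything the pipeline consumes can be generated here: an LD reference panel
(latent AR(1) Gaussian dichotomized to haplotypes, default 5000 individuals),
two-sample exposure/outcome GWAS summary statistics from disjoint cohorts,
discovery/replication dataset pairs of unequal size, tissue-expression
matrices, and the small annotation fixtures (gene regions, drug annotation
text, phenome-scan phenotypes).

Two simulation routes are provided:

* **individual-level** (`simulate_panel`, `simulate_gwas`): cohorts of
  genotypes are drawn and marginal regressions run per variant, exactly as a
  GWAS would. Binary outcomes use a one-step score approximation to
  per-variant logistic regression (`method="score"`, default) or full
  per-variant logistic fits (`method="logistic"`); the two agree closely for
  the modest effects simulated here.
* **summary-level** (`simulate_instrument_set`, `simulate_region_pair`):
  estimates are drawn directly from their asymptotic sampling distribution
  (beta_hat ~ N(R b_joint, se^2 R)), which is exact in the large-n limit and
  orders of magnitude faster — used for replicate-heavy calibration studies.

All generators take explicit seeds/generators and are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import GeneRegion, InstrumentSet
from .sumstats import LDMatrix, ReferencePanel, SumStats, VariantKey, sumstats_from_arrays

#: non-palindromic allele pairs cycled over simulated variants
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Effects are on the standardized-genotype scale: ``causal_effects`` maps
    each exposure name to {variant index: effect in exposure-SD units};
    ``direct_effects`` maps variant index to a direct log-odds effect on the
    outcome (horizontal pleiotropy / target-mediated disease effects);
    ``theta`` maps exposure name to its causal log-odds effect per SD.
    """

    n_variants: int = 60
    n_ref: int = 5000
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    exposure_names: tuple[str, ...] = ("LDL-C",)
    causal_effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    direct_effects: Mapping[int, float] = field(default_factory=dict)
    theta: Mapping[str, float] = field(default_factory=dict)
    exposure_resid_corr: float = 0.2
    case_fraction: float = 0.3
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        for name in self.causal_effects:
            if name not in self.exposure_names:
                raise ValueError(f"causal effects for unknown exposure '{name}'")
            for i in self.causal_effects[name]:
                if not (0 <= i < self.n_variants):
                    raise ValueError(f"causal index {i} out of range")

    def variant_keys(self, mafs=None) -> list[VariantKey]:
        keys = []
        for j in range(self.n_variants):
            ea, oa = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
            keys.append(VariantKey(self.chrom, self.pos_start + j * self.pos_step, ea, oa))
        return keys


def ar1_matrix(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r[i, j] = rho^|i - j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def dichotomized_corr(rho: float, maf1: float, maf2: float) -> float:
    """Correlation of two Bernoulli alleles from a dichotomized bivariate normal.

    Alleles are indicator(z < Phi^-1(maf)) on latent normals with correlation
    ``rho``. Used as the theoretical check for the panel generator.
    """
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    p11 = stats.multivariate_normal.cdf([t1, t2], mean=[0, 0],
                                        cov=[[1, rho], [rho, 1]])
    num = p11 - maf1 * maf2
    den = math.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return float(num / den)


def _latent_ar1(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * math.sqrt(1 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def _draw_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray,
                  rho: float) -> np.ndarray:
    """n x m dosage matrix: two dichotomized-AR(1) haplotypes summed."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    h1 = _latent_ar1(rng, n, m, rho) < thresh
    h2 = _latent_ar1(rng, n, m, rho) < thresh
    return (h1.astype(np.float64) + h2)


def simulate_panel(cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> tuple[ReferencePanel, LDMatrix]:
    """Simulate the LD reference panel and its empirical dosage LD matrix."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, cfg.n_variants)
    dosages = _draw_dosages(rng, cfg.n_ref, mafs, cfg.rho)
    keys = cfg.variant_keys()
    panel = ReferencePanel(dosages=dosages, variants=keys, maf=mafs,
                           info=np.ones(cfg.n_variants),
                           gprob=np.ones(cfg.n_variants))
    from .sumstats import compute_ld
    return panel, compute_ld(panel)


def _marginal_ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant simple linear regression of y on each dosage column."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ss_g = np.einsum("ij,ij->j", gc, gc)
    beta = (gc.T @ yc) / ss_g
    ss_y = float(yc @ yc)
    resid_var = np.maximum(ss_y - beta ** 2 * ss_g, 1e-12) / (n - 2)
    se = np.sqrt(resid_var / ss_g)
    return beta, se


def _marginal_logistic_score(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-step score approximation to per-variant logistic regression."""
    ybar = y.mean()
    gc = G - G.mean(axis=0)
    V = ybar * (1 - ybar) * np.einsum("ij,ij->j", gc, gc)
    U = gc.T @ (y - ybar)
    return U / V, 1.0 / np.sqrt(V)


def _marginal_logistic_full(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    betas, ses = [], []
    ones = np.ones((len(y), 1))
    for j in range(G.shape[1]):
        X = np.column_stack([ones, G[:, j]])
        fit = sm.Logit(y, X).fit(disp=0)
        betas.append(fit.params[1])
        ses.append(fit.bse[1])
    return np.array(betas), np.array(ses)


def simulate_gwas(panel: ReferencePanel, cfg: SimConfig,
                  rng: np.random.Generator | None = None,
                  n_exposure: int | None = None, n_outcome: int | None = None,
                  method: Literal["score", "logistic"] = "score",
                  ) -> tuple[list[SumStats], SumStats]:
    """Two-sample GWAS: marginal summary statistics from disjoint cohorts.

    A fresh exposure cohort and a fresh outcome cohort are drawn with the same
    latent LD process as the panel (two-sample independence by construction).
    Exposure phenotypes are unit-variance: sum of standardized-dosage causal
    effects plus (correlated) Gaussian noise. The binary outcome follows a
    logistic model whose liability combines exposure values through ``theta``
    and per-variant direct effects.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_exp = n_exposure or cfg.n_exposure
    n_out = n_outcome or cfg.n_outcome
    mafs = panel.maf
    keys = panel.variants
    m = len(keys)
    k_exp = len(cfg.exposure_names)

    B = np.zeros((m, k_exp))
    for e, name in enumerate(cfg.exposure_names):
        for i, b in cfg.causal_effects.get(name, {}).items():
            B[i, e] = b

    def _phenotypes(G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        Gs = (G - G.mean(axis=0)) / np.maximum(G.std(axis=0), 1e-12)
        genetic = Gs @ B
        gvar = genetic.var(axis=0)
        resid_sd = np.sqrt(np.maximum(1.0 - gvar, 0.05))
        C = np.full((k_exp, k_exp), cfg.exposure_resid_corr)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        eps = rng.standard_normal((len(G), k_exp)) @ L.T
        return genetic + eps * resid_sd, Gs

    # exposure cohort
    G_exp = _draw_dosages(rng, n_exp, mafs, cfg.rho)
    X, _ = _phenotypes(G_exp, rng)
    exposures = []
    for e, name in enumerate(cfg.exposure_names):
        beta, se = _marginal_ols(G_exp, X[:, e])
        p = 2 * stats.norm.sf(np.abs(beta / se))
        exposures.append(sumstats_from_arrays(
            name, "quantitative",
            [k.chrom for k in keys], [k.pos for k in keys],
            [k.effect_allele for k in keys], [k.other_allele for k in keys],
            beta, se, p, G_exp.mean(axis=0) / 2.0, np.full(m, n_exp)))

    # outcome cohort (independent draw)
    G_out = _draw_dosages(rng, n_out, mafs, cfg.rho)
    X_out, Gs_out = _phenotypes(G_out, rng)
    d = np.zeros(m)
    for i, v in cfg.direct_effects.items():
        d[i] = v
    th = np.array([cfg.theta.get(name, 0.0) for name in cfg.exposure_names])
    alpha = math.log(cfg.case_fraction / (1 - cfg.case_fraction))
    liability = alpha + X_out @ th + Gs_out @ d
    y = (rng.uniform(size=n_out) < 1.0 / (1.0 + np.exp(-liability))).astype(float)

    fn = _marginal_logistic_score if method == "score" else _marginal_logistic_full
    beta_y, se_y = fn(G_out, y)
    p_y = 2 * stats.norm.sf(np.abs(beta_y / se_y))
    outcome = sumstats_from_arrays(
        "outcome", "binary",
        [k.chrom for k in keys], [k.pos for k in keys],
        [k.effect_allele for k in keys], [k.other_allele for k in keys],
        beta_y, se_y, p_y, G_out.mean(axis=0) / 2.0, np.full(m, n_out))
    return exposures, outcome


def simulate_replication_pair(cfg: SimConfig, panel: ReferencePanel,
                              n_exposure_rep: int, n_outcome_rep: int,
                              rng: np.random.Generator | None = None,
                              replication_cfg: SimConfig | None = None,
                              ) -> tuple[tuple[list[SumStats], SumStats],
                                         tuple[list[SumStats], SumStats]]:
    """A discovery/replication pair: same architecture, independent cohorts.

    The replication arm may override the architecture (``replication_cfg``),
    e.g. to emulate a target whose effect does not transfer across datasets;
    by default it shares the discovery architecture with fresh noise and the
    (typically smaller) replication sample sizes.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    discovery = simulate_gwas(panel, cfg, rng=rng)
    rep_cfg = replication_cfg or cfg
    replication = simulate_gwas(panel, rep_cfg, rng=rng,
                                n_exposure=n_exposure_rep, n_outcome=n_outcome_rep)
    return discovery, replication


# ---------------------------------------------------------------------------
# summary-level (asymptotic) simulators for replicate-heavy studies
# ---------------------------------------------------------------------------

def simulate_instrument_set(rng: np.random.Generator, n_snps: int, theta: float,
                            n_x: int = 50_000, n_y: int = 50_000,
                            case_fraction: float = 0.3, rho: float = 0.3,
                            bx_range: tuple[float, float] = (0.05, 0.15),
                            intercept: float = 0.0,
                            pleiotropy_sd: float = 0.0,
                            unit: str = "sim") -> InstrumentSet:
    """Draw one instrument set from the asymptotic two-sample MR model.

    True exposure effects |b_x| ~ U(bx_range) (standardized scale, clumped
    variants with residual AR(1) LD ``rho``); estimates are sampled as
    b_x_hat ~ N(b_x, s_x^2 R) and b_y_hat ~ N(theta b_x + a + e, s_y^2 R)
    with per-variant pleiotropy e ~ N(0, pleiotropy_sd^2) and directional
    pleiotropy intercept ``a``.
    """
    R = ar1_matrix(n_snps, rho)
    Lr = np.linalg.cholesky(R + np.eye(n_snps) * 1e-12)
    bx = rng.uniform(*bx_range, n_snps) * rng.choice([-1.0, 1.0], n_snps)
    sx = np.full(n_snps, 1.0 / math.sqrt(n_x))
    phi = case_fraction * (1 - case_fraction)
    sy = np.full(n_snps, 1.0 / math.sqrt(n_y * phi))
    pleio = rng.standard_normal(n_snps) * pleiotropy_sd if pleiotropy_sd else 0.0
    bx_hat = bx + sx * (Lr @ rng.standard_normal(n_snps))
    # directional pleiotropy acts relative to the exposure-raising allele
    by_true = theta * bx + intercept * np.sign(bx) + pleio
    by_hat = by_true + sy * (Lr @ rng.standard_normal(n_snps))

    keys = [VariantKey("1", 1_000_000 + 2_000 * j, "A", "G") for j in range(n_snps)]
    pairs = pd.DataFrame({
        "chrom": "1", "pos": [k.pos for k in keys],
        "effect_allele": "A", "other_allele": "G", "rsid": None,
        "beta_x": bx_hat, "se_x": sx, "pvalue_x": 2 * stats.norm.sf(np.abs(bx_hat / sx)),
        "eaf_x": 0.3, "n_x": float(n_x),
        "beta_y": by_hat, "se_y": sy, "pvalue_y": 2 * stats.norm.sf(np.abs(by_hat / sy)),
        "eaf_y": 0.3, "n_y": float(n_y),
    })
    return InstrumentSet(unit=unit, exposure_trait="exposure", outcome_trait="outcome",
                         pairs=pairs, ld=LDMatrix(keys, R))


def simulate_region_sumstats(rng: np.random.Generator, m: int, rho: float, n: int,
                             causal: Mapping[int, float],
                             trait: str = "exposure",
                             trait_type: str = "quantitative",
                             case_fraction: float = 0.3,
                             maf: float | np.ndarray = 0.3,
                             chrom: str = "1", pos_start: int = 1_000_000,
                             pos_step: int = 2_000,
                             R: np.ndarray | None = None,
                             ) -> tuple[SumStats, LDMatrix]:
    """Summary statistics for one region drawn from their asymptotic law.

    Marginal standardized effects are R @ b_joint; estimates are sampled with
    covariance se^2 R and converted to the per-allele scale through
    sd_g = sqrt(2 maf (1 - maf)).
    """
    R = ar1_matrix(m, rho) if R is None else R
    mafs = np.broadcast_to(np.asarray(maf, float), (m,))
    b_joint = np.zeros(m)
    for i, b in causal.items():
        b_joint[i] = b
    b_marg = R @ b_joint
    se_std = (1.0 / math.sqrt(n) if trait_type == "quantitative"
              else 1.0 / math.sqrt(n * case_fraction * (1 - case_fraction)))
    Lr = np.linalg.cholesky(R + np.eye(m) * 1e-12)
    b_hat = b_marg + se_std * (Lr @ rng.standard_normal(m))
    sd_g = np.sqrt(2 * mafs * (1 - mafs))
    beta_allele = b_hat / sd_g
    se_allele = se_std / sd_g
    p = 2 * stats.norm.sf(np.abs(b_hat / se_std))

    keys = [VariantKey(chrom, pos_start + pos_step * j, *_ALLELE_CYCLE[j % 4])
            for j in range(m)]
    ss = sumstats_from_arrays(
        trait, trait_type, [k.chrom for k in keys], [k.pos for k in keys],
        [k.effect_allele for k in keys], [k.other_allele for k in keys],
        beta_allele, se_allele, p, mafs, np.full(m, float(n)))
    return ss, LDMatrix(keys, R)


def simulate_region_pair(rng: np.random.Generator, m: int, rho: float,
                         n_x: int, n_y: int,
                         causal_x: Mapping[int, float],
                         causal_y: Mapping[int, float],
                         case_fraction: float = 0.3,
                         maf: float = 0.3) -> tuple[SumStats, SumStats, LDMatrix]:
    """Exposure and outcome summary statistics over one region with shared LD."""
    R = ar1_matrix(m, rho)
    ex, ld = simulate_region_sumstats(rng, m, rho, n_x, causal_x, trait="exposure",
                                      trait_type="quantitative", maf=maf, R=R)
    oy, _ = simulate_region_sumstats(rng, m, rho, n_y, causal_y, trait="outcome",
                                     trait_type="binary",
                                     case_fraction=case_fraction, maf=maf, R=R)
    return ex, oy, ld


# ---------------------------------------------------------------------------
# expression and annotation fixtures
# ---------------------------------------------------------------------------

def simulate_expression(rng: np.random.Generator, genes: Sequence[str],
                        tissues: Sequence[str],
                        patterns: Mapping[str, str] | None = None,
                        dominant_fold: float = 10.0) -> list:
    """Per-gene NX profiles: one-hot, uniform, or graded with a dominant tissue.

    one-hot genes have tau = 1 exactly; uniform genes tau = 0; graded genes
    draw log-normal NX with one tissue boosted ``dominant_fold``-fold.
    """
    from .tissue import ExpressionProfile

    patterns = patterns or {}
    out = []
    for g in genes:
        pat = patterns.get(g, "graded")
        if pat == "one-hot":
            nx = np.zeros(len(tissues))
            nx[rng.integers(len(tissues))] = rng.uniform(20, 80)
        elif pat == "uniform":
            nx = np.full(len(tissues), float(rng.uniform(5, 50)))
        else:
            nx = rng.lognormal(mean=1.0, sigma=0.5, size=len(tissues))
            nx[rng.integers(len(tissues))] *= dominant_fold
        out.append(ExpressionProfile(g, nx, list(tissues)))
    return out


@dataclass
class FixtureBundle:
    """A self-contained synthetic study exercising every pipeline stage."""

    panel: ReferencePanel
    ld: LDMatrix
    exposures: list[SumStats]
    outcome: SumStats
    exposures_rep: list[SumStats]
    outcome_rep: SumStats
    genes: list[GeneRegion]
    expression: list
    drug_annotations: pd.DataFrame
    phenotypes: list[SumStats]
    config: SimConfig
    truth: dict


#: the bundled synthetic study's gene table:
#: (symbol, lipid, target disease slope per lipid SD, druggable, role)
STUDY_GENES = [
    ("TG0A", "LDL-C", 0.7, True, "positive control: replicates and colocalizes"),
    ("TG1B", "LDL-C", 0.6, True, "discordant: disease effect reversed in replication"),
    ("TG2C", "HDL-C", 0.0, True, "coloc negative control: distinct outcome variant"),
    ("TG3D", "HDL-C", -0.8, True, "protective HDL-raising target"),
    ("TG4E", "TG", 0.8, True, "triglyceride target"),
    ("TG5F", "LDL-C", 0.7, False, "not druggable: must never be reported"),
    ("TG6G", "LDL-C", 0.9, True, "strong LDL target"),
    ("TG7H", "LDL-C", 1.1, True, "strong LDL target"),
    ("TG8I", "HDL-C", -0.6, True, "moderate HDL target"),
    ("TG9J", "TG", 1.2, True, "strong TG target"),
    ("TG10K", "LDL-C", 0.0, True, "null target: lipid signal, no disease effect"),
]

#: lead-variant lipid effect in exposure-SD units (~1.4% variance explained,
#: the scale of major lipid loci at genes encoding drugged targets)
LEAD_EFFECT = 0.12


def default_study_config(seed: int = 0, n_exposure: int = 20_000,
                         n_outcome: int = 20_000) -> tuple[SimConfig, list[GeneRegion], dict]:
    """The bundled synthetic study: eleven gene regions, three lipid exposures.

    Each region holds 30 variants at 5 kb spacing (so a gene's +/-50 kb
    window stays inside its own region) with the lipid-causal lead at offset
    15 explaining ~1.4% of exposure variance. A target's effect on disease is
    a direct log-odds effect at its lead variant equal to ``slope x lipid
    effect`` — the vertical pathway a drug on that target would perturb. See
    ``STUDY_GENES`` for the gene table, including the discordant-replication
    and colocalization negative controls.
    """
    region, lead = 30, 15
    pos0, step = 1_000_000, 5_000
    genes = []
    for g, (name, _lipid, _slope, drug, _role) in enumerate(STUDY_GENES):
        start = pos0 + (g * region + 10) * step
        end = pos0 + (g * region + 20) * step
        genes.append(GeneRegion(f"G{g}", name, "1", start, end, flank=50_000,
                                druggable=drug))

    def li(g):  # lead index of region g
        return g * region + lead

    b = LEAD_EFFECT
    causal: dict[str, dict[int, float]] = {"LDL-C": {}, "HDL-C": {}, "TG": {}}
    direct: dict[int, float] = {}
    slopes = {}
    for g, (_name, lipid, slope, _drug, _role) in enumerate(STUDY_GENES):
        causal[lipid][li(g)] = b
        slopes[g] = slope
        if slope != 0.0:
            direct[li(g)] = slope * b
    direct[li(2) - 10] = b  # TG2C: outcome signal at a distinct variant
    cfg = SimConfig(
        n_variants=len(STUDY_GENES) * region, n_ref=5000, rho=0.8,
        maf_range=(0.05, 0.5), n_exposure=n_exposure, n_outcome=n_outcome,
        exposure_names=("LDL-C", "HDL-C", "TG"),
        causal_effects=causal, direct_effects=direct, seed=seed,
        pos_start=pos0, pos_step=step,
    )
    truth = {"slopes": slopes,
             "lead_index": {g: li(g) for g in range(len(STUDY_GENES))},
             "region_size": region,
             "lipid_of_gene": {g: rec[1] for g, rec in enumerate(STUDY_GENES)}}
    return cfg, genes, truth


def make_fixtures(seed: int = 0, n_exposure: int = 20_000, n_outcome: int = 20_000,
                  n_exposure_rep: int = 8_000, n_outcome_rep: int = 30_000,
                  outdir=None) -> FixtureBundle:
    """Build the full synthetic study bundle (optionally writing TSVs).

    The replication arm reuses the discovery architecture except for the
    discordant-control gene, whose disease effect is reversed — emulating a
    finding that fails to transfer across datasets. The replication exposure
    cohort is smaller than discovery and the replication outcome cohort
    larger, mirroring the shape of typical discovery/replication designs
    (a modest biomarker panel paired with a biobank-scale disease GWAS).
    """
    cfg, genes, truth = default_study_config(seed, n_exposure, n_outcome)
    rng = np.random.default_rng(seed)
    panel, ld = simulate_panel(cfg, rng)

    rep_direct = dict(cfg.direct_effects)
    # discordant control: disease effect reversed in the replication datasets
    rep_direct[truth["lead_index"][1]] = -truth["slopes"][1] * LEAD_EFFECT
    rep_cfg = SimConfig(**{**cfg.__dict__, "direct_effects": rep_direct})
    (exposures, outcome), (exposures_rep, outcome_rep) = simulate_replication_pair(
        cfg, panel, n_exposure_rep, n_outcome_rep, rng=rng, replication_cfg=rep_cfg)

    tissues = ["liver", "kidney", "brain", "heart", "lung", "intestine",
               "muscle", "blood", "skin", "pancreas"]
    patterns = {"TG0A": "one-hot", "TG1B": "uniform"}
    expression = simulate_expression(rng, [g.symbol for g in genes], tissues, patterns)

    drug_annotations = pd.DataFrame([
        {"gene": "TG0A", "source": "registry", "category": "indication",
         "text": "Hypercholesterolemia; mixed dyslipidemia", "affected": np.nan},
        {"gene": "TG3D", "source": "formulary", "category": "adverse event",
         "text": "hyperlipidaemia reported", "affected": 3},
        {"gene": "TG4E", "source": "registry", "category": "adverse event",
         "text": "elevated triglycerides", "affected": 0},
        {"gene": "TG1B", "source": "registry", "category": "indication",
         "text": "hypertension", "affected": np.nan},
    ])

    # phenome-scan phenotypes: one with a planted signal in TG0A, one null
    m = cfg.n_variants
    pheno_rng = np.random.default_rng(seed + 7)
    planted, _ = simulate_region_sumstats(
        pheno_rng, m, cfg.rho, 100_000, {truth["lead_index"][0]: 0.05},
        trait="type 2 diabetes", trait_type="binary", maf=panel.maf,
        pos_start=cfg.pos_start, pos_step=cfg.pos_step, R=ld.r)
    null_ph, _ = simulate_region_sumstats(
        pheno_rng, m, cfg.rho, 100_000, {}, trait="null phenotype",
        trait_type="binary", maf=panel.maf, pos_start=cfg.pos_start,
        pos_step=cfg.pos_step, R=ld.r)
    bundle = FixtureBundle(panel=panel, ld=ld, exposures=exposures, outcome=outcome,
                           exposures_rep=exposures_rep, outcome_rep=outcome_rep,
                           genes=genes, expression=expression,
                           drug_annotations=drug_annotations,
                           phenotypes=[planted, null_ph], config=cfg, truth=truth)
    if outdir is not None:
        write_fixture_tsvs(bundle, outdir)
    return bundle


def write_fixture_tsvs(bundle: FixtureBundle, outdir) -> None:
    """Write the bundle in the TSV dialects the readers consume."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    groups = [("", bundle.exposures + [bundle.outcome]),
              ("rep_", bundle.exposures_rep + [bundle.outcome_rep]),
              ("pheno_", bundle.phenotypes)]
    for tag, group in groups:
        for s in group:
            safe = s.trait.replace(" ", "_").replace("/", "-")
            s.table.to_csv(out / f"sumstats_{tag}{safe}.tsv", sep="\t", index=False)
    pd.DataFrame({
        "chrom": [g.chrom for g in bundle.genes],
        "start": [g.start for g in bundle.genes],
        "end": [g.end for g in bundle.genes],
        "gene_id": [g.gene_id for g in bundle.genes],
        "symbol": [g.symbol for g in bundle.genes],
        "druggable": [int(g.druggable) for g in bundle.genes],
    }).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {t: [p.nx[i] for p in bundle.expression]
         for i, t in enumerate(bundle.expression[0].tissues)},
        index=[p.gene_id for p in bundle.expression],
    ).rename_axis("gene_id").to_csv(out / "expression_nx.tsv", sep="\t")
    bundle.drug_annotations.to_csv(out / "drug_annotations.tsv", sep="\t", index=False)
    ld_df = pd.DataFrame(bundle.ld.r,
                         columns=[v.ident for v in bundle.ld.variants])
    ld_df.to_csv(out / "ld_matrix.tsv", sep="\t", index=False)
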