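"""LD-aware Mendelian randomization estimation.

The causal effect of an exposure on an outcome is estimated by regressing
per-variant outcome associations (beta_y) on exposure associations (beta_x)
under a generalized-least-squares (GLS) error model that accounts for residual
LD between instruments:

    Sigma = D R D,   D = diag(SE_y),   R = signed LD correlation matrix.

Four competing models are fitted — IVW fixed, IVW random, Egger fixed, Egger
random — and a Ruecker-style framework picks between them: the Egger family
is chosen when the drop in Cochran's Q from freeing the intercept exceeds the
chi-square(1) critical value (directional pleiotropy), and random effects are
used when the chosen family's residual heterogeneity is itself significant.

Uncertainty in beta_x is ignored (first-order two-sample approximation), so
weak instruments attenuate estimates toward the null; this is documented, not
corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, stats

from .errors import (
    CollinearityError,
    ConditioningError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    UndefinedHeterogeneityError,
)
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MRModel:
    family: Literal["ivw", "egger"]
    effects: Literal["fixed", "random"]

    def __post_init__(self):
        if self.family not in ("ivw", "egger") or self.effects not in ("fixed", "random"):
            raise ValueError(f"invalid MR model: {self.family}/{self.effects}")

    def __str__(self) -> str:
        return f"{self.family}-{self.effects}"


@dataclass
class MREstimate:
    """Causal-slope estimate for one analysis unit.

    ``beta`` is the log-OR (binary outcome) or mean difference per SD of the
    exposure; ``or_`` is exp(beta).
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q: float
    q_df: int
    q_pvalue: float
    n_snps: int
    model: MRModel
    unit: str = ""
    exposure: str = ""
    outcome: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class MVMREstimate:
    """Joint (direct) effects of several exposures from a single GLS regression."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    q: float
    q_df: int
    q_pvalue: float
    n_snps: int
    effects: str = "fixed"

    def or_(self) -> np.ndarray:
        return np.exp(self.beta)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-instrument causal estimate by/bx with first-order delta-method SE.

    se = sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for bx = 0")
    ratio = by / bx
    se = math.sqrt(sy * sy / (bx * bx) + by * by * sx * sx / bx ** 4)
    return ratio, se


def _sigma_solver(sy: np.ndarray, R: np.ndarray, ridge_eps: float = 1e-8):
    """Cholesky factor of Sigma = D R D with escalating ridge on R's diagonal.

    Ridge escalates x10 from ``ridge_eps`` up to 1e-4; beyond that the system
    is declared ill-conditioned.
    """
    D = np.asarray(sy, float)
    # try the unregularized system first so well-conditioned fits are exact
    try:
        return linalg.cholesky(R * np.outer(D, D), lower=True)
    except linalg.LinAlgError:
        pass
    eps = ridge_eps
    while eps <= 1e-4 + 1e-12:
        Rreg = R + np.eye(len(D)) * eps
        sigma = Rreg * np.outer(D, D)
        try:
            L = linalg.cholesky(sigma, lower=True)
            return L
        except linalg.LinAlgError:
            eps *= 10
    raise ConditioningError(
        f"LD-weighted covariance is singular even after ridge 1e-4 (n={len(D)})")


def _gls(X: np.ndarray, y: np.ndarray, L: np.ndarray):
    """GLS solve given the Cholesky factor L of Sigma. Returns (coef, cov, q, resid)."""
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    try:
        cov = linalg.inv(xtx)
    except linalg.LinAlgError:
        raise CollinearityError("singular design in GLS fit",
                                condition_number=float(np.linalg.cond(X)))
    coef = cov @ (Xw.T @ yw)
    resid_w = yw - Xw @ coef
    q = float(resid_w @ resid_w)
    return coef, cov, q, resid_w


def gls_fit(instr: InstrumentSet, family: Literal["ivw", "egger"] = "ivw",
            effects: Literal["fixed", "random"] = "fixed",
            ridge_eps: float = 1e-8) -> MREstimate:
    """Fit one of the four MR models on an instrument set.

    IVW regresses beta_y on beta_x through the origin; Egger adds a free
    intercept capturing average directional pleiotropy. Egger inputs are first
    oriented so every beta_x >= 0 (beta_y sign-flipped in step). Random
    effects multiply all variances by max(1, Q / (n - k)).
    """
    n = instr.n_snps
    if family == "egger" and n < 3:
        raise InsufficientInstrumentsError(f"Egger regression needs >= 3 variants, got {n}")
    if n < 1:
        raise InsufficientInstrumentsError("no instruments")

    bx, by, sy = instr.bx().copy(), instr.by().copy(), instr.sy()
    R = instr.ld.r
    if family == "egger":
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx = bx * flip
        by = by * flip
        R = R * np.outer(flip, flip)
        X = np.column_stack([np.ones(n), bx])
        slope_idx, k = 1, 2
    else:
        X = bx.reshape(-1, 1)
        slope_idx, k = 0, 1

    L = _sigma_solver(sy, R, ridge_eps)
    coef, cov, q, _ = _gls(X, y=by, L=L)

    df = n - k
    q_pvalue = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    scale = 1.0
    if effects == "random" and df > 0:
        scale = max(1.0, q / df)

    beta = float(coef[slope_idx])
    se = float(math.sqrt(cov[slope_idx, slope_idx] * scale))
    z = beta / se if se > 0 else float("inf")
    pvalue = float(2 * stats.norm.sf(abs(z)))
    est = MREstimate(
        beta=beta, se=se, ci_low=beta - Z975 * se, ci_high=beta + Z975 * se,
        pvalue=pvalue, q=q, q_df=max(df, 0), q_pvalue=q_pvalue, n_snps=n,
        model=MRModel(family, effects), unit=instr.unit_label,
        exposure=instr.exposure_trait, outcome=instr.outcome_trait,
    )
    if family == "egger":
        i_se = float(math.sqrt(cov[0, 0] * scale))
        est.intercept = float(coef[0])
        est.intercept_se = i_se
        est.intercept_pvalue = float(2 * stats.norm.sf(abs(est.intercept) / i_se)) \
            if i_se > 0 else float("nan")
    return est


def cochran_q(instr: InstrumentSet, fit: MREstimate,
              ridge_eps: float = 1e-8) -> tuple[float, int, float, np.ndarray]:
    """Cochran's Q for a fitted model, with per-variant contributions.

    Q = (beta_y - X beta_hat)' Sigma^-1 (beta_y - X beta_hat); df = n - k.
    Contributions are the squared whitened residuals (which reduce to the
    per-variant quadratic-form shares under identity LD).
    """
    n = instr.n_snps
    k = 2 if fit.model.family == "egger" else 1
    df = n - k
    if df <= 0:
        raise UndefinedHeterogeneityError(f"Q undefined: n_snps={n}, parameters={k}")

    bx, by, sy = instr.bx().copy(), instr.by().copy(), instr.sy()
    R = instr.ld.r
    if fit.model.family == "egger":
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        R = R * np.outer(flip, flip)
        pred = fit.intercept + fit.beta * bx
    else:
        pred = fit.beta * bx
    L = _sigma_solver(sy, R, ridge_eps)
    resid_w = linalg.solve_triangular(L, by - pred, lower=True)
    contributions = resid_w ** 2
    q = float(contributions.sum())
    return q, df, float(stats.chi2.sf(q, df)), contributions


def _leverage(instr: InstrumentSet, family: str, ridge_eps: float = 1e-8) -> np.ndarray:
    """Diagonal of the GLS hat matrix in the whitened coordinate system."""
    n = instr.n_snps
    bx, sy = instr.bx().copy(), instr.sy()
    R = instr.ld.r
    if family == "egger":
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx = bx * flip
        R = R * np.outer(flip, flip)
        X = np.column_stack([np.ones(n), bx])
    else:
        X = bx.reshape(-1, 1)
    L = _sigma_solver(sy, R, ridge_eps)
    Xw = linalg.solve_triangular(L, X, lower=True)
    qm, _ = np.linalg.qr(Xw)
    return np.einsum("ij,ij->i", qm, qm)


def select_model(instr: InstrumentSet, alpha_q: float = 0.05,
                 ridge_eps: float = 1e-8) -> MREstimate:
    """Pick among the four competing models (Ruecker-style).

    Starting from fixed-effect IVW:

    * If IVW's Q shows significant heterogeneity (p < ``alpha_q``) and the
      drop Q_IVW - Q_Egger exceeds the chi-square(1) critical value at
      ``alpha_q``, the heterogeneity is attributed to directional pleiotropy
      and the Egger family is used (requires >= 3 variants; with fewer, IVW
      is forced).
    * Within the chosen family, random effects are used iff that family's Q
      p-value < ``alpha_q``.
    """
    n = instr.n_snps
    if n == 1:
        return gls_fit(instr, "ivw", "fixed", ridge_eps)

    ivw = gls_fit(instr, "ivw", "fixed", ridge_eps)
    family = "ivw"
    if n >= 3 and ivw.q_df > 0 and ivw.q_pvalue < alpha_q:
        egger = gls_fit(instr, "egger", "fixed", ridge_eps)
        crit = stats.chi2.ppf(1 - alpha_q, 1)
        if ivw.q - egger.q > crit:
            family = "egger"
    chosen_fixed = ivw if family == "ivw" else egger
    effects = "random" if (chosen_fixed.q_df > 0
                           and chosen_fixed.q_pvalue < alpha_q) else "fixed"
    if effects == "fixed":
        return chosen_fixed
    return gls_fit(instr, family, "random", ridge_eps)


def prune_outliers(instr: InstrumentSet, q_alpha: float = 0.001,
                   leverage_mult: float = 3.0,
                   alpha_q: float = 0.05) -> InstrumentSet:
    """Remove heterogeneity outliers and high-leverage instruments.

    While the currently selected model shows significant global heterogeneity
    (Cochran's Q p-value < ``q_alpha``), one variant is removed per
    iteration: a high-leverage variant (hat leverage > ``leverage_mult`` x
    mean leverage) if any exists — the one with the largest Q contribution —
    otherwise the variant with the largest Q contribution outright. The model
    is re-selected after every removal; pruning never goes below 1 variant
    (IVW) / 3 (Egger) and leaves well-fitting sets untouched (a dominant but
    consistent instrument is not removed).
    """
    current = instr
    while True:
        fit = select_model(current, alpha_q=alpha_q)
        n = current.n_snps
        floor = 3 if fit.model.family == "egger" else 1
        if n <= floor:
            return current
        try:
            q, df, q_p, contrib = cochran_q(current, fit)
        except UndefinedHeterogeneityError:
            return current
        if q_p >= q_alpha:
            return current
        lev = _leverage(current, fit.model.family)
        offenders = np.flatnonzero(lev > leverage_mult * lev.mean())
        pool = offenders if offenders.size else np.arange(n)
        worst = int(pool[np.argmax(contrib[pool])])
        logger.debug("prune_outliers: removing %s (Q p=%.2e, contribution %.2f, "
                     "leverage %.3f)", current.ld.variants[worst].ident, q_p,
                     contrib[worst], lev[worst])
        current = current.subset([i for i in range(n) if i != worst])


def mvmr_fit(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, ld_r: np.ndarray,
             exposures: Sequence[str],
             effects: Literal["fixed", "random"] = "fixed",
             ridge_eps: float = 1e-8,
             cond_max: float = 1e8) -> MVMREstimate:
    """Multivariable MR: joint GLS of beta_y on several exposures' beta_x.

    Parameters
    ----------
    bx : (n_snps, n_exposures) matrix of exposure associations
    by, sy : outcome associations and SEs, length n_snps
    ld_r : signed LD matrix over the same variants

    The design has no intercept; heterogeneity Q over the joint fit is
    reported as evidence of residual horizontal pleiotropy.
    """
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == len(by) and bx.ndim == 2:
        X = bx
    else:
        X = bx.T
    n, p = X.shape
    if n < p + 1:
        raise InsufficientInstrumentsError(
            f"MVMR needs >= {p + 1} variants for {p} exposures, got {n}")
    cond = float(np.linalg.cond(X))
    if not np.isfinite(cond) or cond > cond_max:
        raise CollinearityError(
            f"rank-deficient MVMR design (condition number {cond:.3g})",
            condition_number=cond)

    L = _sigma_solver(np.asarray(sy, float), np.asarray(ld_r, float), ridge_eps)
    coef, cov, q, _ = _gls(X, np.asarray(by, float), L)
    df = n - p
    q_pvalue = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    scale = max(1.0, q / df) if (effects == "random" and df > 0) else 1.0

    se = np.sqrt(np.diag(cov) * scale)
    z = np.divide(coef, se, out=np.full_like(coef, np.inf), where=se > 0)
    return MVMREstimate(
        exposures=list(exposures), beta=coef, se=se,
        ci_low=coef - Z975 * se, ci_high=coef + Z975 * se,
        pvalue=2 * stats.norm.sf(np.abs(z)),
        q=q, q_df=max(df, 0), q_pvalue=q_pvalue, n_snps=n, effects=effects,
    )
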