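"""GWAS summary statistics: containers, readers, reference-panel QC, LD, harmonization.

Conventions
-----------
* Coordinates are 1-based inclusive on GRCh37 throughout.
* ``beta`` is the effect per copy of the *effect allele*: per-SD units for
  quantitative traits, log-odds for binary traits.
* Variants are matched across datasets by (chrom, pos, allele set) rather than
  rsid, because rsid versions drift between consortium releases.
* All record dropping is log-and-continue: drop counts are returned alongside
  the data, never swallowed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateVariantError, FormatError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names used internally
SUMSTATS_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "rsid",
                    "beta", "se", "pvalue", "eaf", "n"]

#: default mapping from common header names to canonical names
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "chrom", "chr": "chrom", "chromosome": "chrom",
    "pos": "pos", "bp": "pos", "position": "pos", "base_pair_location": "pos",
    "effect_allele": "effect_allele", "ea": "effect_allele", "a1": "effect_allele",
    "other_allele": "other_allele", "oa": "other_allele", "a2": "other_allele",
    "rsid": "rsid", "snp": "rsid", "variant_id": "rsid", "id": "rsid",
    "beta": "beta", "b": "beta", "effect": "beta",
    "se": "se", "standard_error": "se", "stderr": "se",
    "pvalue": "pvalue", "p": "pvalue", "pval": "pvalue", "p_value": "pvalue",
    "eaf": "eaf", "effect_allele_frequency": "eaf", "freq": "eaf", "af": "eaf",
    "n": "n", "samplesize": "n", "sample_size": "n",
}


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: position plus the allele pair it is reported on."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect and other allele identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def ident(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.effect_allele}:{self.other_allele}"

    def is_palindromic(self) -> bool:
        """A/T or C/G variants cannot be strand-resolved from alleles alone."""
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class SumStats:
    """One trait's per-variant association estimates.

    ``table`` holds one row per variant with the canonical columns
    (chrom, pos, effect_allele, other_allele, rsid, beta, se, pvalue, eaf, n).
    """

    trait: str
    trait_type: Literal["quantitative", "binary"]
    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"SumStats table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def scale(self) -> str:
        return "per-SD" if self.trait_type == "quantitative" else "log-odds"

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def keys(self) -> list[VariantKey]:
        return [VariantKey(str(r.chrom), int(r.pos), r.effect_allele, r.other_allele,
                           r.rsid if isinstance(r.rsid, str) else None)
                for r in self.table.itertuples()]

    def maf(self) -> np.ndarray:
        eaf = self.table["eaf"].to_numpy(float)
        return np.minimum(eaf, 1.0 - eaf)

    def slice_region(self, chrom: str, start: int, end: int) -> "SumStats":
        """Variants with start <= pos <= end on ``chrom`` (1-based inclusive)."""
        t = self.table
        sub = t[(t["chrom"].astype(str) == str(chrom)) & (t["pos"] >= start) & (t["pos"] <= end)]
        return SumStats(self.trait, self.trait_type, sub.copy())


@dataclass
class LDMatrix:
    """Signed pairwise correlation over an ordered variant list.

    ``r[i, j]`` is the correlation between dosages of variants i and j, signed
    relative to the effect alleles of ``variants``.
    """

    variants: list[VariantKey]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        n = len(self.variants)
        if self.r.shape != (n, n):
            raise AlignmentError(f"LD matrix shape {self.r.shape} != variant count {n}")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("LD entries outside [-1, 1]")
        self._index = {v.ident: i for i, v in enumerate(self.variants)}

    def subset(self, keys: Sequence[VariantKey]) -> "LDMatrix":
        idx = [self._index[k.ident] for k in keys]
        return LDMatrix(list(keys), self.r[np.ix_(idx, idx)])

    def r2(self) -> np.ndarray:
        return self.r ** 2

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.r)[0])


@dataclass
class ReferencePanel:
    """Individual-level dosage panel used to estimate LD.

    dosages: individuals x variants, allele dosages in [0, 2] (NaN = missing).
    """

    dosages: np.ndarray
    variants: list[VariantKey]
    maf: np.ndarray
    info: np.ndarray
    gprob: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape[1] != len(self.variants):
            raise AlignmentError("dosage column count != variant count")
        for name in ("maf", "info", "gprob"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (len(self.variants),):
                raise AlignmentError(f"{name} length != variant count")
            setattr(self, name, v)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None,
                  trait: str = "trait",
                  trait_type: Literal["quantitative", "binary"] = "quantitative",
                  sep: str = "\t") -> tuple[SumStats, int]:
    """Read a delimited summary-statistics table.

    Parameters
    ----------
    dialect
        Maps file column names to canonical names. Merged over a permissive
        default dialect, so only unusual headers need mapping.

    Returns
    -------
    (SumStats, n_dropped)
        Rows violating record invariants (se <= 0, eaf outside (0,1),
        pvalue outside (0,1], non-finite beta) are dropped and counted.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update({k.lower(): v for k, v in dialect.items()})

    with _open_maybe_gzip(path) as fh:
        try:
            raw = pd.read_csv(fh, sep=sep)
        except pd.errors.EmptyDataError:
            raise FormatError(f"empty summary-statistics file: {path}")
    if raw.empty:
        raise FormatError(f"summary-statistics file has a header but no rows: {path}")

    renamed = raw.rename(columns={c: mapping.get(c.lower(), c.lower()) for c in raw.columns})
    required = [c for c in SUMSTATS_COLUMNS if c != "rsid"]
    missing = [c for c in required if c not in renamed.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    if "rsid" not in renamed.columns:
        renamed["rsid"] = None

    t = renamed[SUMSTATS_COLUMNS].copy()
    t["chrom"] = t["chrom"].astype(str)
    for c in ("beta", "se", "pvalue", "eaf"):
        t[c] = pd.to_numeric(t[c], errors="coerce")
    t["pos"] = pd.to_numeric(t["pos"], errors="coerce")
    t["n"] = pd.to_numeric(t["n"], errors="coerce")
    for c in ("effect_allele", "other_allele"):
        t[c] = t[c].astype(str).str.upper()

    ok = (
        np.isfinite(t["beta"]) & (t["se"] > 0)
        & (t["pvalue"] > 0) & (t["pvalue"] <= 1)
        & (t["eaf"] > 0) & (t["eaf"] < 1)
        & (t["pos"] >= 1)
        & (t["effect_allele"] != t["other_allele"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid record(s)", path, n_dropped)
    t = t[ok].reset_index(drop=True)
    t["pos"] = t["pos"].astype(int)
    return SumStats(trait, trait_type, t), n_dropped


def sumstats_from_arrays(trait: str, trait_type: str, chrom, pos, effect_allele,
                         other_allele, beta, se, pvalue, eaf, n,
                         rsid=None) -> SumStats:
    """Build a SumStats container from parallel arrays (simulation/test helper)."""
    k = len(pos)
    table = pd.DataFrame({
        "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (k,)).astype(str),
        "pos": np.asarray(pos, int),
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "rsid": rsid if rsid is not None else [None] * k,
        "beta": np.asarray(beta, float),
        "se": np.asarray(se, float),
        "pvalue": np.asarray(pvalue, float),
        "eaf": np.asarray(eaf, float),
        "n": np.asarray(n, float),
    })
    return SumStats(trait, trait_type, table)


def qc_reference(panel: ReferencePanel) -> tuple[ReferencePanel, int]:
    """Tiered MAF/quality filter for the LD reference panel.

    Retains exactly the variants passing all of:

    * maf >= 0.001 and info >= 0.3
    * not (maf < 0.005 and gprob < 0.9)
    * not (maf < 0.01 and gprob < 0.8)
    * not (maf < 0.03 and gprob < 0.6)

    so lower-frequency variants must meet progressively stricter genotype
    certainty. Returns the filtered panel and the number removed.
    """
    maf, info, gprob = panel.maf, panel.info, panel.gprob
    keep = (
        (maf >= 0.001) & (info >= 0.3)
        & ~((maf < 0.005) & (gprob < 0.9))
        & ~((maf < 0.01) & (gprob < 0.8))
        & ~((maf < 0.03) & (gprob < 0.6))
    )
    idx = np.flatnonzero(keep)
    out = ReferencePanel(
        dosages=panel.dosages[:, idx],
        variants=[panel.variants[i] for i in idx],
        maf=maf[idx], info=info[idx], gprob=gprob[idx],
    )
    n_removed = len(panel.variants) - len(idx)
    if n_removed:
        logger.info("qc_reference: removed %d variant(s)", n_removed)
    return out, n_removed


def compute_ld(panel: ReferencePanel, subset: Sequence[VariantKey] | None = None) -> LDMatrix:
    """Pearson correlation of dosage columns, signed relative to effect alleles.

    Missing dosages are mean-imputed per variant (deterministic, standard
    reference-panel practice). A zero-variance column raises
    :class:`DegenerateVariantError` naming the variant.
    """
    if subset is None:
        keys = list(panel.variants)
        idx = np.arange(len(keys))
    else:
        index = {v.ident: i for i, v in enumerate(panel.variants)}
        try:
            idx = np.array([index[k.ident] for k in subset], int)
        except KeyError as e:
            raise AlignmentError(f"variant {e} not in reference panel")
        keys = list(subset)
    if panel.n_individuals < 2:
        raise DegenerateVariantError("need >= 2 individuals to compute LD")

    X = panel.dosages[:, idx].copy()
    # mean-impute missing dosages per variant
    col_means = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateVariantError(
            f"zero-variance dosage column for variant {keys[zero[0]].ident}")
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return LDMatrix(keys, r)


def _allele_state(ea_x, oa_x, ea_y, oa_y) -> str | None:
    """Classify outcome alleles relative to exposure: same, swap, strand, strand_swap."""
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)
    if (cea, coa) == (ea_x, oa_x):
        return "strand"
    if (cea, coa) == (oa_x, ea_x):
        return "strand_swap"
    return None


def harmonize(exposure: SumStats, outcome: SumStats, palindrome_maf: float = 0.3,
              palindrome_mode: Literal["align", "drop_all"] = "align",
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align outcome effects to exposure effect alleles.

    Variants are joined on (chrom, pos). Swapped alleles get a sign flip and
    eaf complement; strand-flipped alleles (A<->T, C<->G complements of the
    exposure pair) are reconciled first. Palindromic variants (A/T, C/G):

    * ``align`` (default): dropped when MAF >= ``palindrome_maf`` in either
      dataset; below the threshold, aligned by comparing which allele is minor.
    * ``drop_all``: every palindromic variant is removed.

    Returns
    -------
    (pairs, log)
        ``pairs`` has one row per retained variant with columns
        chrom, pos, effect_allele, other_allele, rsid,
        beta_x, se_x, pvalue_x, eaf_x, n_x, beta_y, se_y, pvalue_y, eaf_y, n_y.
        ``log`` counts drops by reason.
    """
    ex = exposure.table.add_suffix("_x").rename(columns={"chrom_x": "chrom", "pos_x": "pos"})
    oy = outcome.table.add_suffix("_y").rename(columns={"chrom_y": "chrom", "pos_y": "pos"})
    merged = ex.merge(oy, on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise AlignmentError(
            f"no shared chrom/pos between '{exposure.trait}' and '{outcome.trait}'")

    log = {"irreconcilable_alleles": 0, "palindromic_high_maf": 0, "palindromic": 0}
    rows = []
    for r in merged.itertuples():
        state = _allele_state(r.effect_allele_x, r.other_allele_x,
                              r.effect_allele_y, r.other_allele_y)
        if state is None:
            log["irreconcilable_alleles"] += 1
            logger.debug("harmonize: irreconcilable alleles at %s:%s", r.chrom, r.pos)
            continue
        beta_y, eaf_y = r.beta_y, r.eaf_y
        if state in ("swap", "strand_swap"):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y

        palindromic = COMPLEMENT.get(r.effect_allele_x) == r.other_allele_x
        if palindromic:
            if palindrome_mode == "drop_all":
                log["palindromic"] += 1
                continue
            maf_x = min(r.eaf_x, 1 - r.eaf_x)
            maf_y = min(eaf_y, 1 - eaf_y)
            if maf_x >= palindrome_maf or maf_y >= palindrome_maf:
                log["palindromic_high_maf"] += 1
                continue
            # align by frequency: the effect allele should be minor (or major)
            # in both datasets; a mismatch implies the outcome is on the other strand
            if (r.eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        rows.append({
            "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele_x, "other_allele": r.other_allele_x,
            "rsid": r.rsid_x,
            "beta_x": r.beta_x, "se_x": r.se_x, "pvalue_x": r.pvalue_x,
            "eaf_x": r.eaf_x, "n_x": r.n_x,
            "beta_y": beta_y, "se_y": r.se_y, "pvalue_y": r.pvalue_y,
            "eaf_y": eaf_y, "n_y": r.n_y,
        })
    dropped = sum(log.values())
    if dropped:
        logger.info("harmonize(%s vs %s): dropped %d variant(s): %s",
                    exposure.trait, outcome.trait, dropped, log)
    cols = ["chrom", "pos", "effect_allele", "other_allele", "rsid",
            "beta_x", "se_x", "pvalue_x", "eaf_x", "n_x",
            "beta_y", "se_y", "pvalue_y", "eaf_y", "n_y"]
    pairs = pd.DataFrame(rows, columns=cols)
    return pairs, log


def pairs_keys(pairs: pd.DataFrame) -> list[VariantKey]:
    """VariantKeys of a harmonized pairs table, in row order."""
    return [VariantKey(str(r.chrom), int(r.pos), r.effect_allele, r.other_allele,
                       rsid if isinstance(rsid := getattr(r, "rsid", None), str) else None)
            for r in pairs.itertuples()]
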