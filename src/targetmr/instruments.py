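"""Instrument selection: significance/MAF filters, greedy LD clumping, and
druggable-gene region mapping.

Genome-wide instruments use p <= 1e-6; gene-centric (*cis*) instruments use
p <= 1e-4 within the gene body +/- 50 kb. Both filter MAF > 0.01 and thin
correlated variants by greedy clumping at r^2 < 0.4 — the parameter
combination that behaved most consistently across positive-control targets
in a window/LD grid search (see :func:`grid_search_calibration`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInstrumentError
from .sumstats import LDMatrix, SumStats, VariantKey, pairs_keys

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A gene body on GRCh37 (1-based inclusive) with a flanking window."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    flank: int = 50_000
    druggable: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")
        if self.flank < 0:
            raise ValueError(f"gene {self.symbol}: negative flank")

    @property
    def window(self) -> tuple[int, int]:
        """The flanked interval [start - flank, end + flank], clipped at 1."""
        return max(1, self.start - self.flank), self.end + self.flank

    def distance_to(self, pos: int) -> int:
        """0 inside the gene body, else distance to the nearer gene edge."""
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass
class GeneVariantMap:
    """Variants mapped to one gene: (key, distance_bp, distance_rank).

    ``distance_rank`` ranks this gene among all genes overlapping the same
    variant, 1 = nearest.
    """

    gene: GeneRegion
    variants: list[tuple[VariantKey, int, int]] = field(default_factory=list)


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effects plus LD for one analysis unit.

    ``pairs`` rows and ``ld.variants`` index the same ordered variant list.
    """

    unit: str | GeneRegion
    exposure_trait: str
    outcome_trait: str
    pairs: pd.DataFrame
    ld: LDMatrix

    def __post_init__(self):
        if len(self.pairs) != len(self.ld.variants):
            raise ValueError("pairs and LD matrix have different variant counts")
        got = [k.ident for k in pairs_keys(self.pairs)]
        want = [v.ident for v in self.ld.variants]
        if got != want:
            raise ValueError("pairs and LD matrix are not aligned on the same variants")

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def unit_label(self) -> str:
        return self.unit if isinstance(self.unit, str) else self.unit.symbol

    def bx(self) -> np.ndarray:
        return self.pairs["beta_x"].to_numpy(float)

    def sx(self) -> np.ndarray:
        return self.pairs["se_x"].to_numpy(float)

    def by(self) -> np.ndarray:
        return self.pairs["beta_y"].to_numpy(float)

    def sy(self) -> np.ndarray:
        return self.pairs["se_y"].to_numpy(float)

    def subset(self, idx: Sequence[int]) -> "InstrumentSet":
        idx = list(idx)
        return InstrumentSet(
            unit=self.unit, exposure_trait=self.exposure_trait,
            outcome_trait=self.outcome_trait,
            pairs=self.pairs.iloc[idx].reset_index(drop=True),
            ld=self.ld.subset([self.ld.variants[i] for i in idx]),
        )


def ld_clump(candidates: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.4) -> list[int]:
    """Greedy LD clumping of a candidate table.

    Scans candidates by ascending p-value (ties broken by chrom, pos) and
    keeps a variant iff its r^2 with every already-kept variant is strictly
    below ``r2_max``. Returns positional indices into ``candidates`` in the
    kept order. Deterministic and invariant to input row order.
    """
    keys = pairs_keys(candidates) if "beta_x" in candidates.columns else [
        VariantKey(str(r.chrom), int(r.pos), r.effect_allele, r.other_allele)
        for r in candidates.itertuples()]
    pcol = "pvalue_x" if "pvalue_x" in candidates.columns else "pvalue"
    p = candidates[pcol].to_numpy(float)
    order = sorted(range(len(keys)), key=lambda i: (p[i], keys[i].chrom, keys[i].pos))
    idx_in_ld = {v.ident: i for i, v in enumerate(ld.variants)}
    r2 = ld.r2()
    kept: list[int] = []
    for i in order:
        li = idx_in_ld[keys[i].ident]
        if all(r2[li, idx_in_ld[keys[j].ident]] < r2_max for j in kept):
            kept.append(i)
    return kept


def _build_instrument_set(unit, exposure_trait, outcome_trait, pairs, ld,
                          p_max, maf_min, r2_max, stage) -> InstrumentSet:
    maf = np.minimum(pairs["eaf_x"].to_numpy(float), 1 - pairs["eaf_x"].to_numpy(float))
    mask = (pairs["pvalue_x"].to_numpy(float) <= p_max) & (maf > maf_min)
    cand = pairs[mask].reset_index(drop=True)
    if cand.empty:
        raise EmptyInstrumentError(stage)
    kept = ld_clump(cand, ld, r2_max)
    cand = cand.iloc[kept].reset_index(drop=True)
    # keep genomic order for readability; clumping is order-invariant anyway
    cand = cand.sort_values(["chrom", "pos"]).reset_index(drop=True)
    sub_ld = ld.subset(pairs_keys(cand))
    return InstrumentSet(unit=unit, exposure_trait=exposure_trait,
                         outcome_trait=outcome_trait, pairs=cand, ld=sub_ld)


def select_genomewide(pairs: pd.DataFrame, ld: LDMatrix,
                      exposure_trait: str, outcome_trait: str,
                      p_max: float = 1e-6, maf_min: float = 0.01,
                      r2_max: float = 0.4) -> InstrumentSet:
    """Genome-wide instrument selection on a harmonized pairs table.

    Retains variants with exposure p-value <= ``p_max`` and MAF > ``maf_min``,
    then greedily clumps to pairwise r^2 < ``r2_max``.
    """
    return _build_instrument_set("genome-wide", exposure_trait, outcome_trait,
                                 pairs, ld, p_max, maf_min, r2_max,
                                 stage="select_genomewide")


def select_cis(pairs: pd.DataFrame, ld: LDMatrix, gene: GeneRegion,
               exposure_trait: str, outcome_trait: str,
               p_max: float = 1e-4, maf_min: float = 0.01,
               r2_max: float = 0.4) -> InstrumentSet:
    """Gene-centric (*cis*) instrument selection within the flanked gene window."""
    lo, hi = gene.window
    in_window = ((pairs["chrom"].astype(str) == str(gene.chrom))
                 & (pairs["pos"] >= lo) & (pairs["pos"] <= hi))
    region = pairs[in_window].reset_index(drop=True)
    if region.empty:
        raise EmptyInstrumentError(f"select_cis:{gene.symbol}")
    return _build_instrument_set(gene, exposure_trait, outcome_trait,
                                 region, ld, p_max, maf_min, r2_max,
                                 stage=f"select_cis:{gene.symbol}")


def map_druggable_genes(selected: Sequence[VariantKey],
                        genes: Sequence[GeneRegion],
                        druggable_only: bool = True) -> list[GeneVariantMap]:
    """Map selected variants to (druggable) genes within each gene's window.

    A gene is reported iff at least one selected variant lies within
    [start - flank, end + flank]. Each mapped variant carries its distance to
    the gene (0 inside the body, else base pairs to the nearer edge) and the
    rank of this gene among all genes overlapping that variant (1 = nearest;
    ties broken by gene symbol).
    """
    pool = [g for g in genes if g.druggable] if druggable_only else list(genes)
    # variant -> [(gene, distance)] over candidate genes whose window covers it
    per_variant: dict[str, list[tuple[GeneRegion, int]]] = {}
    for g in pool:
        lo, hi = g.window
        for v in selected:
            if str(v.chrom) == str(g.chrom) and lo <= v.pos <= hi:
                per_variant.setdefault(v.ident, []).append((g, g.distance_to(v.pos)))

    ranks: dict[tuple[str, str], int] = {}
    for ident, hits in per_variant.items():
        for rank, (g, _d) in enumerate(
                sorted(hits, key=lambda t: (t[1], t[0].symbol)), start=1):
            ranks[(ident, g.gene_id)] = rank

    out = []
    for g in pool:
        lo, hi = g.window
        rows = [(v, g.distance_to(v.pos), ranks[(v.ident, g.gene_id)])
                for v in selected
                if str(v.chrom) == str(g.chrom) and lo <= v.pos <= hi]
        if rows:
            out.append(GeneVariantMap(gene=g, variants=rows))
    return out


def grid_search_calibration(pairs: pd.DataFrame, ld: LDMatrix,
                            controls: Sequence[tuple[GeneRegion, int]],
                            windows: Sequence[int], r2s: Sequence[float],
                            exposure_trait: str = "exposure",
                            outcome_trait: str = "outcome",
                            p_max: float = 1e-4,
                            maf_min: float = 0.01) -> pd.DataFrame:
    """Window x LD-threshold consistency table over positive-control genes.

    For each (window, r^2) cell, runs cis selection plus the selected MR model
    for every control gene (a gene region paired with its expected effect
    direction, +1 or -1) and reports the fraction of controls recovering the
    expected direction, the mean |log-OR|/SE, and the instrument counts.
    Cells where a control yields no instruments are recorded as missing, not
    fatal. The table is reported for inspection, never optimized over
    automatically.
    """
    from .mr import select_model  # local import: avoid a module cycle

    if not controls:
        raise ValueError("grid search needs at least one control gene")
    if not windows or not r2s:
        raise ValueError("grid search needs non-empty window and r2 grids")

    rows = []
    for window in windows:
        for r2_max in r2s:
            correct, abs_z, n_snps, missing = [], [], [], 0
            for gene, expected_sign in controls:
                flanked = GeneRegion(gene.gene_id, gene.symbol, gene.chrom,
                                     gene.start, gene.end, flank=int(window),
                                     druggable=gene.druggable)
                try:
                    instr = select_cis(pairs, ld, flanked, exposure_trait,
                                       outcome_trait, p_max=p_max,
                                       maf_min=maf_min, r2_max=r2_max)
                    est = select_model(instr)
                except Exception:
                    missing += 1
                    continue
                correct.append(float(np.sign(est.beta) == np.sign(expected_sign)))
                abs_z.append(abs(est.beta) / est.se if est.se > 0 else np.nan)
                n_snps.append(est.n_snps)
            rows.append({
                "window": int(window), "r2_max": float(r2_max),
                "n_controls": len(controls), "n_missing": missing,
                "fraction_correct_direction": float(np.mean(correct)) if correct else np.nan,
                "mean_abs_z": float(np.mean(abs_z)) if abs_z else np.nan,
                "mean_n_snps": float(np.mean(n_snps)) if n_snps else np.nan,
            })
    return pd.DataFrame(rows)


def read_gene_regions(path, flank: int = 50_000) -> list[GeneRegion]:
    """Read gene annotation from a BED-like TSV.

    Expected columns: chrom, start, end, gene_id, symbol, druggable
    (header required; druggable parsed as 0/1 or true/false).
    Coordinates are taken as 1-based inclusive.
    """
    t = pd.read_csv(path, sep="\t")
    t.columns = [c.lower() for c in t.columns]
    out = []
    for r in t.itertuples():
        drug = str(r.druggable).strip().lower() in ("1", "true", "yes")
        out.append(GeneRegion(str(r.gene_id), str(r.symbol), str(r.chrom),
                              int(r.start), int(r.end), flank=flank, druggable=drug))
    return out
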