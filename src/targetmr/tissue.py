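"""Tissue specificity from a normalized-expression (NX) matrix.

Two complementary metrics per gene:

* **tau** in [0, 1]: 0 for ubiquitously expressed (housekeeping) genes, 1 for
  genes expressed in a single tissue. With x'_i = x_i / max(x):
  tau = sum_i (1 - x'_i) / (n - 1).
* **per-tissue z-scores**: how elevated expression in one tissue is relative
  to the others; tissues with z > 1 (strict) are reported as "top tissues".

Both are computed on log2(x + 1)-transformed values by default, following
common practice in tau benchmarking; the raw-scale variants are exposed via
``log_transform=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedTauError


@dataclass
class ExpressionProfile:
    """One gene's non-negative normalized expression across tissues."""

    gene_id: str
    nx: np.ndarray
    tissues: list[str]

    def __post_init__(self):
        self.nx = np.asarray(self.nx, float)
        if len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues")
        if self.nx.shape != (len(self.tissues),):
            raise ValueError("nx length != tissue count")
        if np.any(self.nx < 0):
            raise ValueError("NX values must be non-negative")


@dataclass
class SpecificityScore:
    gene_id: str
    tau: float
    z: np.ndarray
    tissues: list[str]
    top_tissues: list[tuple[str, float]]  # (tissue, z) with z > 1, descending


def tau(profile: ExpressionProfile, log_transform: bool = True) -> float:
    """Tissue-specificity index tau in [0, 1]."""
    x = profile.nx
    if x.max() == 0:
        raise UndefinedTauError(f"tau undefined for all-zero profile {profile.gene_id}")
    if log_transform:
        x = np.log2(x + 1.0)
    xhat = x / x.max()
    return float(np.sum(1.0 - xhat) / (len(x) - 1))


def tissue_z(profile: ExpressionProfile, log_transform: bool = True,
             z_top: float = 1.0) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Per-tissue z-scores and the tissues with z > ``z_top`` (strict).

    A flat profile (zero SD) yields all-zero z and no top tissue.
    """
    x = profile.nx.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x), []
    z = (x - x.mean()) / sd
    top = sorted(((t, float(zi)) for t, zi in zip(profile.tissues, z) if zi > z_top),
                 key=lambda p: -p[1])
    return z, top


def score_gene(profile: ExpressionProfile, log_transform: bool = True) -> SpecificityScore:
    z, top = tissue_z(profile, log_transform=log_transform)
    return SpecificityScore(gene_id=profile.gene_id,
                            tau=tau(profile, log_transform=log_transform),
                            z=z, tissues=list(profile.tissues), top_tissues=top)


def read_expression(path) -> list[ExpressionProfile]:
    """Read a gene x tissue NX matrix from TSV (first column = gene id)."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    tissues = [str(c) for c in t.columns]
    return [ExpressionProfile(str(g), row.to_numpy(float), tissues)
            for g, row in t.iterrows()]


def specificity_table(profiles: list[ExpressionProfile],
                      log_transform: bool = True) -> pd.DataFrame:
    """Gene-level specificity report: tau plus top tissues (z > 1)."""
    rows = []
    for p in profiles:
        try:
            s = score_gene(p, log_transform=log_transform)
        except UndefinedTauError:
            rows.append({"gene_id": p.gene_id, "tau": np.nan, "top_tissues": ""})
            continue
        rows.append({
            "gene_id": s.gene_id, "tau": s.tau,
            "top_tissues": ", ".join(f"{t} ({z:.2f})" for t, z in s.top_tissues),
        })
    return pd.DataFrame(rows)
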