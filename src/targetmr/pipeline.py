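"""End-to-end orchestration of the drug-target MR pipeline.

Stages (each a pure function over the in-memory study bundle):

1. ``genomewide`` — genome-wide biomarker MR per lipid (p <= 1e-6 instruments)
2. ``mvmr``       — joint multivariable MR of the lipid fractions
3. ``cis``        — per-(gene x lipid) drug-target MR on discovery data
4. ``replication``— the same cis analysis on the replication datasets,
                    plus directional concordance of significant estimates
5. ``coloc``      — per-gene colocalization of lipid and disease signals
6. ``tissue``     — tau / z-score tissue specificity
7. ``annotations``— keyword matching of drug-annotation text
8. ``phewas``     — region-based phenome scan
9. ``report``     — merged prioritization table

Every run writes flat TSVs plus a JSON manifest (parameters, seed, config
hash, drop counts) so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import prioritize as pri
from .errors import DependencyError, EmptyInstrumentError, TargetMRError
from .instruments import select_cis, select_genomewide
from .mr import mvmr_fit, prune_outliers, select_model
from .simulate import FixtureBundle, make_fixtures
from .sumstats import SumStats, harmonize
from .tissue import specificity_table

logger = logging.getLogger(__name__)

ALL_STAGES = ["genomewide", "mvmr", "cis", "replication", "coloc", "tissue",
              "annotations", "phewas", "report"]


@dataclass
class RunConfig:
    """All thresholds of the pipeline, with their documented defaults."""

    seed: int = 0
    outdir: str | None = None
    p_max_genomewide: float = 1e-6
    p_max_cis: float = 1e-4
    maf_min: float = 0.01
    r2_max: float = 0.4
    flank_bp: int = 50_000
    q_alpha: float = 0.001
    alpha: float = 0.05
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_min: float = 0.8
    p_gw: float = 5e-8
    palindrome_maf: float = 0.3
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    n_exposure_rep: int = 8_000
    n_outcome_rep: int = 30_000

    def __post_init__(self):
        checks = [0 < self.p_max_genomewide < 1, 0 < self.p_max_cis < 1,
                  0 <= self.maf_min < 0.5, 0 < self.r2_max <= 1,
                  self.flank_bp >= 0, 0 < self.q_alpha < 1, 0 < self.alpha < 1,
                  0 < self.pp4_min < 1, 0 < self.p_gw < 1]
        if not all(checks):
            raise ValueError("RunConfig threshold outside its documented domain")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _estimate_row(est, gene, lipid):
    lo, hi = est.or_ci
    return {
        "unit": gene, "lipid": lipid, "model": str(est.model),
        "n_snps": est.n_snps, "beta": est.beta, "se": est.se,
        "or": est.or_, "or_ci_low": lo, "or_ci_high": hi,
        "pvalue": est.pvalue, "intercept": est.intercept,
        "intercept_p": est.intercept_pvalue,
        "q": est.q, "q_df": est.q_df, "q_pvalue": est.q_pvalue,
    }


def _cis_scan(exposures: list[SumStats], outcome: SumStats, ld, genes, cfg: RunConfig):
    """Per-(gene x lipid) selected-model MR after outlier/leverage pruning."""
    rows, estimates, harmonized = [], {}, {}
    for exposure in exposures:
        pairs, _ = harmonize(exposure, outcome, palindrome_maf=cfg.palindrome_maf)
        harmonized[exposure.trait] = pairs
        for gene in genes:
            if not gene.druggable:
                continue
            try:
                instr = select_cis(pairs, ld, gene, exposure.trait, outcome.trait,
                                   p_max=cfg.p_max_cis, maf_min=cfg.maf_min,
                                   r2_max=cfg.r2_max)
            except EmptyInstrumentError:
                continue
            instr = prune_outliers(instr, q_alpha=cfg.q_alpha, alpha_q=cfg.alpha)
            est = select_model(instr, alpha_q=cfg.alpha)
            estimates[(gene.symbol, exposure.trait)] = est
            rows.append(_estimate_row(est, gene.symbol, exposure.trait))
    return pd.DataFrame(rows), estimates, harmonized


def run_pipeline(config: RunConfig, bundle: FixtureBundle | None = None,
                 stages: list[str] | None = None) -> dict:
    """Run the requested pipeline stages and return the result bundle.

    ``bundle`` defaults to the bundled synthetic study generated from
    ``config.seed``. Stage dependencies are enforced: requesting a downstream
    stage without its upstream raises :class:`DependencyError`.
    """
    stages = list(ALL_STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    needs = {"replication": "cis", "report": "cis"}
    for stage, upstream in needs.items():
        if stage in stages and upstream not in stages:
            raise DependencyError(stage, upstream)

    if bundle is None:
        bundle = make_fixtures(config.seed, n_exposure=config.n_exposure,
                               n_outcome=config.n_outcome,
                               n_exposure_rep=config.n_exposure_rep,
                               n_outcome_rep=config.n_outcome_rep)
    results: dict = {"config": config, "bundle": bundle}
    genes = bundle.genes
    ld = bundle.ld

    if "genomewide" in stages:
        rows = []
        for exposure in bundle.exposures:
            pairs, _ = harmonize(exposure, bundle.outcome,
                                 palindrome_maf=config.palindrome_maf)
            try:
                instr = select_genomewide(pairs, ld, exposure.trait, "outcome",
                                          p_max=config.p_max_genomewide,
                                          maf_min=config.maf_min,
                                          r2_max=config.r2_max)
            except EmptyInstrumentError:
                continue
            instr = prune_outliers(instr, q_alpha=config.q_alpha, alpha_q=config.alpha)
            est = select_model(instr, alpha_q=config.alpha)
            rows.append(_estimate_row(est, "genome-wide", exposure.trait))
        results["genomewide"] = pd.DataFrame(rows)

    if "mvmr" in stages:
        # union of each lipid's genome-wide instruments, one joint regression
        merged = None
        for exposure in bundle.exposures:
            pairs, _ = harmonize(exposure, bundle.outcome,
                                 palindrome_maf=config.palindrome_maf)
            cols = pairs[["chrom", "pos", "effect_allele", "other_allele",
                          "beta_x", "se_x", "pvalue_x", "eaf_x",
                          "beta_y", "se_y"]].rename(
                columns={"beta_x": f"bx_{exposure.trait}",
                         "se_x": f"sx_{exposure.trait}",
                         "pvalue_x": f"px_{exposure.trait}"})
            merged = cols if merged is None else merged.merge(
                cols.drop(columns=["beta_y", "se_y", "eaf_x"]),
                on=["chrom", "pos", "effect_allele", "other_allele"])
        pcols = [f"px_{e.trait}" for e in bundle.exposures]
        maf = np.minimum(merged["eaf_x"], 1 - merged["eaf_x"])
        keep = (merged[pcols].min(axis=1) <= config.p_max_genomewide) & \
               (maf > config.maf_min)
        cand = merged[keep].reset_index(drop=True)
        cand["pvalue"] = cand[pcols].min(axis=1)
        from .instruments import ld_clump
        kept = ld_clump(cand, ld, config.r2_max)
        cand = cand.iloc[kept].sort_values(["chrom", "pos"]).reset_index(drop=True)
        from .sumstats import pairs_keys
        sub_ld = ld.subset(pairs_keys(cand))
        bx = cand[[f"bx_{e.trait}" for e in bundle.exposures]].to_numpy()
        est = mvmr_fit(bx, cand["beta_y"].to_numpy(), cand["se_y"].to_numpy(),
                       sub_ld.r, [e.trait for e in bundle.exposures])
        results["mvmr"] = pd.DataFrame({
            "exposure": est.exposures, "beta": est.beta, "se": est.se,
            "or": est.or_(), "or_ci_low": np.exp(est.ci_low),
            "or_ci_high": np.exp(est.ci_high), "pvalue": est.pvalue,
            "q": est.q, "q_df": est.q_df, "q_pvalue": est.q_pvalue,
            "n_snps": est.n_snps,
        })

    if "cis" in stages:
        table, estimates, harmonized = _cis_scan(
            bundle.exposures, bundle.outcome, ld, genes, config)
        results["cis"] = table
        results["_cis_estimates"] = estimates
        results["_harmonized"] = harmonized

    if "replication" in stages:
        rep_table, rep_estimates, _ = _cis_scan(
            bundle.exposures_rep, bundle.outcome_rep, ld, genes, config)
        results["replication"] = rep_table
        discovery = [pri.orient(est, lipid, alpha=config.alpha)
                     for (g, lipid), est in results["_cis_estimates"].items()]
        replication = [pri.orient(est, lipid, alpha=config.alpha)
                       for (g, lipid), est in rep_estimates.items()]
        if discovery and replication:
            try:
                results["concordance"] = pri.replication_concordance(
                    discovery, replication, alpha=config.alpha)
            except TargetMRError as e:
                logger.warning("concordance skipped: %s", e)
        results["quartiles"] = pri.summarize_quartiles(discovery)
        disc_p = [e.base.pvalue for e in discovery]
        if len(disc_p) >= 5:
            d, p = pri.ks_uniformity(disc_p)
            results["ks_uniformity"] = {"D": d, "pvalue": p, "n": len(disc_p)}

    if "coloc" in stages:
        priors = coloc_mod.ColocPriors(config.coloc_p1, config.coloc_p2,
                                       config.coloc_p12)
        rows = []
        for exposure in bundle.exposures:
            for gene in genes:
                if not gene.druggable:
                    continue
                lo, hi = gene.window
                ex_region = exposure.slice_region(gene.chrom, lo, hi)
                oy_region = bundle.outcome.slice_region(gene.chrom, lo, hi)
                # only colocalize where the lipid actually has a signal
                if ex_region.table.empty or \
                        ex_region.table["pvalue"].min() > config.p_max_cis:
                    continue
                try:
                    res_list = coloc_mod.colocalize_region(
                        ex_region, oy_region, ld, priors=priors,
                        pp4_min=config.pp4_min, maf_min=config.maf_min)
                except TargetMRError:
                    continue
                for res in res_list:
                    rows.append({
                        "gene": gene.symbol, "lipid": exposure.trait,
                        "signal": res.signal_index,
                        "lead": res.lead.ident if res.lead else None,
                        **{f"pp{i}": res.pp[i] for i in range(5)},
                        "n_variants": res.n_variants,
                        "colocalized": res.colocalized(config.pp4_min),
                    })
        results["coloc"] = pd.DataFrame(rows)

    if "tissue" in stages:
        results["tissue"] = specificity_table(bundle.expression)

    if "annotations" in stages:
        matches = pri.match_annotations(
            [g.symbol for g in genes if g.druggable], bundle.drug_annotations)
        results["annotations"] = pd.DataFrame(
            [{"gene": m.gene, "source": m.source, "category": m.category,
              "keyword": m.keyword, "matched_text": m.matched_text}
             for m in matches])

    if "phewas" in stages:
        results["phewas"] = pri.phewas_scan(
            [g for g in genes if g.druggable], bundle.phenotypes,
            flank=config.flank_bp, p_gw=config.p_gw,
            palindrome_maf=config.palindrome_maf)

    if "report" in stages:
        results["report"] = _build_report(results, config)

    if config.outdir:
        _write_outputs(results, config)
    return results


def _build_report(results: dict, config: RunConfig) -> pd.DataFrame:
    """Merge cis MR, replication, coloc, tissue, and annotation evidence."""
    cis = results.get("cis")
    if cis is None or cis.empty:
        return pd.DataFrame()
    report = cis[["unit", "lipid", "or", "or_ci_low", "or_ci_high",
                  "pvalue", "n_snps", "model"]].rename(columns={
        "or": "discovery_or", "or_ci_low": "discovery_ci_low",
        "or_ci_high": "discovery_ci_high", "pvalue": "discovery_p"})
    conc = results.get("concordance")
    if conc is not None:
        report = report.merge(
            conc.rows[["unit", "lipid", "replication_or", "replication_p",
                       "replication_significant", "concordant"]],
            on=["unit", "lipid"], how="left")
    col = results.get("coloc")
    if col is not None and not col.empty:
        best = (col.groupby(["gene", "lipid"], as_index=False)
                .agg(pp4=("pp4", "max"), colocalized=("colocalized", "any"))
                .rename(columns={"gene": "unit"}))
        report = report.merge(best, on=["unit", "lipid"], how="left")
    tis = results.get("tissue")
    if tis is not None and not tis.empty:
        report = report.merge(tis.rename(columns={"gene_id": "unit"}),
                              on="unit", how="left")
    ann = results.get("annotations")
    if ann is not None and not ann.empty:
        flags = ann.groupby("gene").size().rename("n_annotation_matches")
        report = report.merge(flags, left_on="unit", right_index=True, how="left")
        report["n_annotation_matches"] = report["n_annotation_matches"].fillna(0).astype(int)
    return report


def _write_outputs(results: dict, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "seed": config.seed, "outputs": []}
    for name, obj in results.items():
        if name.startswith("_") or name in ("config", "bundle"):
            continue
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
            manifest["outputs"].append(path.name)
        elif isinstance(obj, dict):
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=float))
            manifest["outputs"].append(path.name)
        elif isinstance(obj, pri.ConcordanceReport):
            path = out / f"{name}.tsv"
            obj.rows.to_csv(path, sep="\t", index=False, float_format="%.10g")
            summary = {
                "n_discovery_significant": obj.n_discovery_significant,
                "n_replication_tested": obj.n_replication_tested,
                "n_replication_significant": obj.n_replication_significant,
                "n_concordant": obj.n_concordant,
                "fraction_concordant": obj.fraction_concordant,
            }
            (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))
            manifest["outputs"] += [path.name, f"{name}_summary.json"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
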