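"""Therapeutic orientation, concordance, quartiles, annotations, PheWAS."""

import math

import numpy as np
import pandas as pd
import pytest

from targetmr.errors import AlignmentError, InsufficientSampleError
from targetmr.instruments import GeneRegion
from targetmr.mr import MREstimate, MRModel
from targetmr.prioritize import (ks_uniformity, match_annotations, orient,
                                 phewas_scan, replication_concordance,
                                 summarize_quartiles)
from targetmr.simulate import simulate_region_sumstats


def estimate(or_, ci=None, p=0.01, unit="GENE"):
    beta = math.log(or_)
    lo, hi = (math.log(ci[0]), math.log(ci[1])) if ci else (beta - 0.2, beta + 0.2)
    se = (hi - beta) / 1.96 if hi > beta else 0.1
    return MREstimate(beta=beta, se=se, ci_low=lo, ci_high=hi, pvalue=p,
                      q=1.0, q_df=4, q_pvalue=0.5, n_snps=5,
                      model=MRModel("ivw", "fixed"), unit=unit)


class TestOrient:
    def test_ldl_or_inverted_to_therapeutic_direction(self):
        o = orient(estimate(1.6, (1.45, 1.77)), "LDL-C")
        assert o.therapeutic_or == pytest.approx(1 / 1.6)
        assert o.beneficial
        assert o.ci_low == pytest.approx(1 / 1.77)
        assert o.ci_high == pytest.approx(1 / 1.45)

    def test_hdl_or_passes_through(self):
        o = orient(estimate(0.91, (0.87, 0.95)), "HDL-C")
        assert o.therapeutic_or == pytest.approx(0.91)
        assert o.beneficial

    def test_protective_ldl_association_flags_harmful_therapy(self):
        o = orient(estimate(0.17, (0.05, 0.59)), "LDL-C")
        assert o.therapeutic_or == pytest.approx(1 / 0.17)
        assert not o.beneficial

    def test_unknown_lipid_rejected(self):
        with pytest.raises(ValueError):
            orient(estimate(1.2), "CRP")

    @pytest.mark.parametrize("lipid,or_", [("LDL-C", 1.7), ("TG", 0.6),
                                           ("HDL-C", 0.8)])
    def test_orientation_is_self_inverse(self, lipid, or_):
        once = orient(estimate(or_), lipid)
        # re-orienting the therapeutic OR must return the original
        back = orient(estimate(once.therapeutic_or), lipid)
        assert back.therapeutic_or == pytest.approx(or_)


class TestKSUniformity:
    def test_near_uniform_grid_has_tiny_statistic(self):
        grid = np.arange(0.01, 1.0, 0.01)
        d, _ = ks_uniformity(grid)
        assert d <= 0.011

    def test_degenerate_mass_rejected(self):
        _, p = ks_uniformity([1e-6] * 100)
        assert p < 1e-10

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(InsufficientSampleError):
            ks_uniformity([0.5, 0.6])

    def test_type_one_error_rate_near_nominal(self, rng):
        rejections = sum(ks_uniformity(rng.uniform(size=200))[1] < 0.05
                        for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


def oriented(unit, lipid, or_, p):
    return orient(estimate(or_, p=p, unit=unit), lipid)


class TestReplicationConcordance:
    def test_identical_lists_fully_concordant(self):
        ests = [oriented(f"G{i}", "LDL-C", 1.5 + 0.1 * i, 0.01) for i in range(4)]
        rep = replication_concordance(ests, ests)
        assert rep.fraction_concordant == 1.0
        assert rep.n_replication_significant == 4

    def test_reciprocal_replication_fully_discordant(self):
        disc = [oriented(f"G{i}", "LDL-C", 1.5, 0.01) for i in range(4)]
        rep_l = [oriented(f"G{i}", "LDL-C", 1 / 1.5, 0.01) for i in range(4)]
        rep = replication_concordance(disc, rep_l)
        assert rep.fraction_concordant == 0.0

    def test_hand_counted_fraction(self):
        disc = [oriented(f"G{i}", "LDL-C", 0.6, 0.01) for i in range(10)]
        # 6 significant replications, 5 concordant (G5 flips direction)
        rep_l = []
        for i in range(10):
            or_ = 2.0 if i == 5 else 0.7
            p = 0.01 if i < 6 else 0.5
            rep_l.append(oriented(f"G{i}", "LDL-C", or_, p))
        rep = replication_concordance(disc, rep_l)
        assert rep.n_replication_significant == 6
        assert rep.n_concordant == 5
        assert rep.fraction_concordant == pytest.approx(5 / 6)

    def test_fraction_invariant_to_unit_order(self, rng):
        disc = [oriented(f"G{i}", "LDL-C", 0.6 + 0.1 * i, 0.01) for i in range(6)]
        rep_l = [oriented(f"G{i}", "LDL-C", 0.5 + 0.2 * i, 0.02) for i in range(6)]
        a = replication_concordance(disc, rep_l).fraction_concordant
        perm = list(rng.permutation(6))
        b = replication_concordance([disc[i] for i in perm],
                                    [rep_l[i] for i in reversed(perm)]
                                    ).fraction_concordant
        assert a == b

    def test_no_overlap_rejected(self):
        with pytest.raises(AlignmentError):
            replication_concordance([oriented("A", "TG", 1.2, 0.01)],
                                    [oriented("B", "TG", 1.2, 0.01)])


class TestQuartiles:
    def test_linear_interpolation_quartiles(self):
        ests = [oriented(f"G{i}", "LDL-C", o, 0.01) for i, o in enumerate([1, 2, 3, 4])]
        t = summarize_quartiles(ests)
        assert t.loc[0, "q1_or"] == pytest.approx(1.75)
        assert t.loc[0, "q3_or"] == pytest.approx(3.25)

    def test_constant_group_collapses(self):
        ests = [oriented(f"G{i}", "TG", 2.0, 0.01) for i in range(5)]
        t = summarize_quartiles(ests)
        assert t.loc[0, "q1_or"] == t.loc[0, "q3_or"] == pytest.approx(2.0)

    def test_small_group_skipped(self):
        ests = [oriented(f"G{i}", "HDL-C", 1.2, 0.01) for i in range(3)]
        assert summarize_quartiles(ests).empty

    def test_only_significant_estimates_counted(self):
        ests = [oriented(f"G{i}", "LDL-C", 2.0, 0.01) for i in range(4)]
        ests += [oriented("G9", "LDL-C", 50.0, 0.9)]  # not significant
        t = summarize_quartiles(ests)
        assert t.loc[0, "n_significant"] == 4
        assert t.loc[0, "q3_or"] == pytest.approx(2.0)


ANNOT = pd.DataFrame([
    {"gene": "A", "source": "registry", "category": "indication",
     "text": "Hypercholesterolemia", "affected": np.nan},
    {"gene": "A", "source": "registry", "category": "adverse event",
     "text": "hyperlipidaemia", "affected": 0},
    {"gene": "B", "source": "formulary", "category": "indication",
     "text": "hypertension", "affected": np.nan},
    {"gene": "C", "source": "registry", "category": "adverse event",
     "text": "elevated triglycerides", "affected": 2},
])


class TestMatchAnnotations:
    def test_stem_matches_inside_word(self):
        hits = match_annotations(["A"], ANNOT.iloc[[0]])
        assert [h.keyword for h in hits] == ["cholest"]

    def test_unrelated_text_not_matched(self):
        assert match_annotations(["B"], ANNOT) == []

    def test_zero_affected_adverse_event_excluded(self):
        hits = match_annotations(["A", "C"], ANNOT)
        assert {h.gene for h in hits if h.category == "adverse event"} == {"C"}

    def test_keyword_list_superset_monotone(self):
        few = match_annotations(["A", "C"], ANNOT, keywords=["lipid"])
        more = match_annotations(["A", "C"], ANNOT,
                                 keywords=["lipid", "cholest", "triglyceride"])
        assert {(h.gene, h.keyword) for h in few} <= \
            {(h.gene, h.keyword) for h in more}

    def test_token_prefix_mode_misses_infix(self):
        hits = match_annotations(["A"], ANNOT.iloc[[0]], keywords=["cholest"],
                                 mode="token_prefix")
        assert hits == []  # 'cholest' is not a token prefix of the word


class TestPhewasScan:
    def _gene(self, start=1_100_000, end=1_120_000):
        return GeneRegion("G", "GENE", "1", start, end, druggable=True)

    def test_planted_association_flagged(self, rng):
        ss, _ = simulate_region_sumstats(rng, 60, 0.8, 200_000, {30: 0.05},
                                         trait="pheno", trait_type="binary",
                                         pos_start=1_000_000, pos_step=5_000)
        gene = GeneRegion("G", "GENE", "1", 1_140_000, 1_160_000, druggable=True)
        t = phewas_scan([gene], [ss])
        assert bool(t.loc[0, "genomewide_significant"])

    def test_null_phenotype_rarely_flagged(self, rng):
        flags = 0
        for _ in range(200):
            ss, _ = simulate_region_sumstats(rng, 100, 0.8, 100_000, {},
                                             trait="null", trait_type="binary",
                                             pos_start=1_000_000, pos_step=1_000)
            t = phewas_scan([self._gene(1_040_000, 1_060_000)], [ss])
            flags += int(t.loc[0, "genomewide_significant"])
        assert flags / 200 < 0.01

    def test_window_boundary_inclusive(self):
        from targetmr.sumstats import sumstats_from_arrays

        gene = self._gene(1_100_000, 1_120_000)
        ss = sumstats_from_arrays("p", "binary", ["1"], [1_100_000 - 50_000],
                                  ["A"], ["G"], [0.1], [0.01], [1e-10], [0.2], [1e5])
        t = phewas_scan([gene], [ss], flank=50_000)
        assert t.loc[0, "n_variants"] == 1
        assert bool(t.loc[0, "genomewide_significant"])

    def test_high_maf_palindromic_variants_removed(self):
        from targetmr.sumstats import sumstats_from_arrays

        gene = self._gene()
        ss = sumstats_from_arrays("p", "binary", ["1", "1"],
                                  [1_105_000, 1_106_000], ["A", "A"],
                                  ["T", "G"], [0.1, 0.0], [0.01, 0.01],
                                  [1e-10, 0.9], [0.45, 0.45], [1e5, 1e5])
        t = phewas_scan([gene], [ss])
        # the significant variant is palindromic with MAF 0.45 -> dropped
        assert t.loc[0, "n_variants"] == 1
        assert not bool(t.loc[0, "genomewide_significant"])

    def test_phenotype_without_region_variants_recorded_missing(self):
        from targetmr.sumstats import sumstats_from_arrays

        ss = sumstats_from_arrays("p", "binary", ["2"], [500], ["A"], ["G"],
                                  [0.1], [0.01], [0.5], [0.2], [1e5])
        t = phewas_scan([self._gene()], [ss])
        assert t.loc[0, "n_variants"] == 0
        assert np.isnan(t.loc[0, "min_p"])
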