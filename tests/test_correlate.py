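import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliomix import correlate as corr
from gliomix.io import ExpressionCohort, SignatureCollection
from gliomix.simulate import SimulationDesign, simulate_multi_cohort

from _oracles import bh_enumeration_oracle


class TestAdjustFdr:
    @pytest.mark.parametrize("p,expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.2,), (0.2,)),
        ((0.005, 0.06, 0.5), (0.015, 0.09, 0.5)),
    ])
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(corr.adjust_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            corr.adjust_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from([0.001, 0.01, 0.04, 0.2, 0.6, 1.0]),
                    min_size=1, max_size=6))
    def test_matches_enumeration_oracle(self, pvals):
        np.testing.assert_allclose(corr.adjust_fdr(pvals),
                                   bh_enumeration_oracle(pvals), atol=1e-12)

    def test_monotone_and_capped(self):
        q = corr.adjust_fdr([0.9, 0.95, 1.0, 0.99])
        assert np.all(q <= 1.0)


def _cohort_from_rows(rows, cohort_id="c"):
    matrix = pd.DataFrame(rows).T
    matrix.columns = [f"s{j}" for j in range(matrix.shape[1])]
    return ExpressionCohort(cohort_id, matrix,
                            probe_to_gene={p: p.split("_")[0] for p in rows})


class TestCorrelateProbes:
    def test_identity_and_anti_identity(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
        cohort = _cohort_from_rows({
            "T_at": t, "SAME_at": t.copy(), "ANTI_at": 10.0 - t})
        recs = {r.probe_id: r for r in corr.correlate_probes(cohort, "T_at")}
        assert recs["SAME_at"].r == pytest.approx(1.0)
        assert recs["ANTI_at"].r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        cohort = _cohort_from_rows({
            "T_at": np.array([1.0, 2.0, 3.0, 4.0]),
            "Y_at": np.array([2.0, 4.0, 5.0, 9.0])})
        rec = next(r for r in corr.correlate_probes(cohort, "T_at")
                   if r.probe_id == "Y_at")
        # by hand: sum(dx*dy)=11, sum(dx^2)=5, sum(dy^2)=26 -> 11/sqrt(130)
        assert rec.r == pytest.approx(11 / np.sqrt(130), abs=1e-12)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            cohort = _cohort_from_rows({"T_at": x, "Y_at": y})
            rec = next(r for r in corr.correlate_probes(cohort, "T_at"))
            sx, sy = x - x.mean(), y - y.mean()
            r_hand = (sx * sy).sum() / np.sqrt((sx ** 2).sum()
                                               * (sy ** 2).sum())
            assert rec.r == pytest.approx(r_hand, abs=1e-12)

    def test_degenerate_probe_flagged_outside_family(self):
        cohort = _cohort_from_rows({
            "T_at": np.arange(5.0), "FLAT_at": np.full(5, 2.0),
            "OK_at": np.arange(5.0) * 2})
        recs = {r.probe_id: r for r in corr.correlate_probes(cohort, "T_at")}
        assert recs["FLAT_at"].degenerate
        assert np.isnan(recs["FLAT_at"].fdr)
        assert not recs["OK_at"].degenerate

    def test_missing_target_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="target"):
            corr.correlate_probes(toy_cohort, "NOPE_at")


def _record(cohort, probe, gene, subtype, r, fdr):
    return corr.CorrelationRecord(cohort_id=cohort, probe_id=probe,
                                  gene=gene, subtype=subtype, r=r,
                                  p_value=fdr / 2, fdr=fdr, n=50)


class TestSilhouette:
    def test_all_non_significant_gives_empty_table(self):
        recs = [_record("c", "a", "A", "MES", 0.5, 1.0)]
        assert corr.build_silhouette(recs).records == []

    def test_r_ascending_within_block(self):
        recs = [_record("c", "a", "A", "MES", 0.3, 0.01),
                _record("c", "b", "B", "MES", 0.1, 0.01)]
        out = corr.build_silhouette(recs)
        assert [r.r for r in out.records] == [0.1, 0.3]

    def test_block_order_follows_supplied_subtype_order(self):
        recs = [_record("c", "a", "A", "PN", -0.2, 0.01),
                _record("c", "b", "B", "MES", 0.4, 0.01),
                _record("c", "c", "C", "MES", 0.2, 0.01)]
        out = corr.build_silhouette(recs, subtype_order=["MES", "PN"])
        assert [r.subtype for r in out.records] == ["MES", "MES", "PN"]
        assert [r.r for r in out.records] == [0.2, 0.4, -0.2]


class TestGeneAggregation:
    def test_single_significant_record_flags_gene(self):
        recs = [_record("c1", "a1", "A", "MES", 0.4, 0.01),
                _record("c2", "a1", "A", "MES", 0.1, 0.9)]
        out = corr.aggregate_gene_level(recs).set_index("gene")
        assert out.loc["A", "flagged"]

    def test_all_null_gene_not_flagged(self):
        recs = [_record("c1", "a1", "A", "MES", 0.4, 0.5)]
        out = corr.aggregate_gene_level(recs).set_index("gene")
        assert not out.loc["A", "flagged"]

    def test_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        genes = ["A", "B", "C"]
        cohorts = ["c1", "c2"]
        recs = []
        for g, c in itertools.product(genes, cohorts):
            for probe_idx in range(2):
                r = float(rng.uniform(-1, 1))
                fdr = float(rng.uniform(0, 0.2))
                recs.append(_record(c, f"{g.lower()}{probe_idx}", g,
                                    "MES", r, fdr))
        out = corr.aggregate_gene_level(recs, direction="positive",
                                        fdr_max=0.05).set_index("gene")
        for g in genes:
            expected = sum(1 for rec in recs
                           if rec.gene == g and rec.fdr < 0.05 and rec.r > 0)
            assert out.loc[g, "n_significant"] == expected

    def test_min_cohort_quorum_boundaries(self):
        def gene_records(gene, n_significant_cohorts):
            recs = []
            for i in range(8):
                fdr = 0.01 if i < n_significant_cohorts else 0.9
                recs.append(_record(f"c{i}", f"{gene}_p", gene, "MES",
                                    0.5, fdr))
            return recs

        recs = gene_records("HIT", 4) + gene_records("MISS", 3)
        out = corr.genes_correlated_in_min_cohorts(recs, min_cohorts=4)
        assert out == ["HIT"]

    def test_quorum_larger_than_cohorts_rejected(self):
        recs = [_record("c1", "a", "A", "MES", 0.5, 0.01)]
        with pytest.raises(ValueError):
            corr.genes_correlated_in_min_cohorts(recs, min_cohorts=4)

    def test_planted_block_recovered_across_cohorts(self):
        """The MES block reaches the 4-of-8 quorum with high Jaccard."""
        jaccards = []
        for seed in range(5):
            design = SimulationDesign(
                seed=seed, sample_counts=(200,) * 8,
                p_true=(0.55,) * 8, mes_corr=(0.4,) * 8,
                n_background_probes=50)
            result = simulate_multi_cohort(design)
            records = []
            for expr, _ in result.cohorts:
                probes = [p for p in expr.probe_ids
                          if p.startswith(("MES", "BG"))]
                records.extend(corr.correlate_probes(
                    expr, design.target_probe, probes=probes))
            hits = set(corr.genes_correlated_in_min_cohorts(records,
                                                            min_cohorts=4))
            planted = {f"MES{i + 1:03d}" for i in range(25)}
            jaccards.append(len(hits & planted) / len(hits | planted))
        assert np.median(jaccards) >= 0.9


class TestSignatureAverageCorrelation:
    def test_scores_identical_to_target_give_r_one(self, toy_cohort):
        scores = pd.Series(toy_cohort.expression("A_at"),
                           index=toy_cohort.sample_ids)
        r, p, per_cohort, n = corr.correlate_signature_averages(
            [(toy_cohort, scores)], "A_at")
        assert r == pytest.approx(1.0)
        assert per_cohort["toy"] == pytest.approx(1.0)
        assert n == toy_cohort.n_samples

    def test_null_background_rarely_significant(self):
        """No planted correlation: background probes pass FDR at median 0."""
        frac = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = {"T_at": rng.normal(size=100)}
            for i in range(500):
                rows[f"BG{i}_at"] = rng.normal(size=100)
            cohort = _cohort_from_rows(rows, cohort_id=f"c{seed}")
            recs = corr.correlate_probes(cohort, "T_at")
            frac.append(np.mean([r.fdr < 0.05 for r in recs
                                 if not r.degenerate]))
        assert np.median(frac) == 0.0
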