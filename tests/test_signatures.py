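import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliomix import signatures as sig
from gliomix.io import ExpressionCohort, SignatureCollection
from gliomix.simulate import (SimulationDesign, signature_gene_sets,
                              simulate_training_cohort)


class TestSignedFoldChange:
    @pytest.mark.parametrize("ratio,expected", [
        (4.0, 4.0), (0.25, -4.0), (1.0, 1.0), (2.5, 2.5), (0.5, -2.0)])
    def test_negative_inverse_convention(self, ratio, expected):
        assert sig.signed_fold_change(ratio) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_ratio_rejected(self, bad):
        with pytest.raises(ValueError):
            sig.signed_fold_change(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 100.0).filter(lambda x: abs(x - 1) > 1e-9))
    def test_reciprocal_antisymmetry(self, x):
        assert sig.signed_fold_change(1.0 / x) == pytest.approx(
            -sig.signed_fold_change(x), rel=1e-9)

    def test_magnitude_always_at_least_one(self):
        for ratio in (0.1, 0.9, 1.0, 1.1, 9.0):
            assert abs(sig.signed_fold_change(ratio)) >= 1.0


def _labeled_cohort(rows: dict, labels: list[str]) -> tuple:
    matrix = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(labels))]).T
    cohort = ExpressionCohort(
        "train", matrix,
        probe_to_gene={p: p.split("_")[0] for p in rows})
    return cohort, pd.Series(labels, index=matrix.columns)


class TestValidateSignatureProbes:
    def _four_group_fixture(self, mes_level=8.0, n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = ["MES"] * n + ["PN"] * n + ["CL"] * n + ["NL"] * n
        base = np.full(4 * n, 4.0)
        planted = base.copy()
        planted[:n] = mes_level
        rows = {
            "GENEA_at": planted + rng.normal(0, noise, 4 * n),
            "GENEB_at": base + rng.normal(0, noise, 4 * n),
        }
        cohort, lab = _labeled_cohort(rows, labels)
        coll = SignatureCollection("sigs", {
            "MES": ["GENEA"], "PN": ["GENEB"], "CL": ["GENEB"],
            "NL": ["GENEB"]})
        return cohort, lab, coll

    def test_planted_probe_hand_arithmetic(self):
        cohort, labels, coll = self._four_group_fixture(noise=0.05, seed=1)
        records, vset = sig.validate_signature_probes(cohort, labels, coll)
        rec = next(r for r in records
                   if r.probe_id == "GENEA_at" and r.subtype == "MES")
        # (2^8) / (3 * 2^4) = 5.33 by hand
        assert rec.subtype_ratio == pytest.approx(256 / 48, rel=0.05)
        assert rec.fold_change == pytest.approx(256 / 48, rel=0.05)
        assert rec.validated
        assert "GENEA_at" in vset.probes["MES"]

    def test_flat_probe_not_validated(self):
        # identical means in all four groups: own/(sum of 3 others) = 1/3,
        # i.e. fold change -3 under the sum-denominator convention; the
        # positive FC > 2 gate still rejects it
        cohort, labels, coll = self._four_group_fixture(noise=0.05, seed=2)
        rec = next(r for r in sig.validate_signature_probes(
            cohort, labels, coll)[0]
            if r.probe_id == "GENEB_at" and r.subtype == "PN")
        assert rec.fold_change == pytest.approx(-3.0, rel=0.05)
        assert not rec.validated

    def test_fold_change_gate_blocks_significant_but_small(self):
        # ratio ~1.26 (< 2) with tiny p must not validate
        rng = np.random.default_rng(3)
        n = 30
        labels = ["MES"] * n + ["PN"] * n + ["CL"] * n + ["NL"] * n
        vals = np.full(4 * n, 6.0)
        vals[:n] = 7.6  # ratio = 2^7.6 / (3*2^6) = 1.01... small but p tiny
        rows = {"GENEA_at": vals + rng.normal(0, 0.05, 4 * n)}
        cohort, lab = _labeled_cohort(rows, labels)
        coll = SignatureCollection("sigs", {"MES": ["GENEA"], "PN": ["GENEA"],
                                            "CL": ["GENEA"], "NL": ["GENEA"]})
        recs, _ = sig.validate_signature_probes(cohort, lab, coll)
        rec = next(r for r in recs if r.subtype == "MES")
        assert rec.t_p_value < 1e-9
        assert rec.fold_change < 2
        assert not rec.validated

    def test_undersized_subtype_rejected(self):
        cohort, labels, coll = self._four_group_fixture()
        labels = labels.copy()
        labels.iloc[:9] = "PN"  # leaves a single MES sample
        with pytest.raises(sig.DesignError, match="MES"):
            sig.validate_signature_probes(cohort, labels, coll)

    def test_generator_mes_block_recovery(self):
        """Planted MES probes validate; background genes never do."""
        design = SimulationDesign(sample_counts=(50,), p_true=(0.55,),
                                  mes_corr=(0.4,), n_background_probes=40)
        coll = SignatureCollection(
            "planted",
            {**signature_gene_sets(design),
             "MES_BG": [f"BG{i + 1:04d}" for i in range(40)]})
        mes_rates, bg_hits = [], 0
        for seed in range(20):
            d = SimulationDesign(**{**design.__dict__, "seed": seed})
            training, labels = simulate_training_cohort(d, n_per_subtype=20)
            # background genes smuggled into a fake subtype must not pass
            coll_run = SignatureCollection("planted", {
                s: list(g) for s, g in signature_gene_sets(d).items()})
            coll_run.sets["MES"] = coll_run.sets["MES"] + \
                [f"BG{i + 1:04d}" for i in range(40)]
            records, vset = sig.validate_signature_probes(training, labels,
                                                          coll_run)
            planted = [f"MES{i + 1:03d}_at" for i in range(25)]
            mes_rates.append(
                np.mean([p in vset.probes["MES"] for p in planted]))
            bg_hits += sum(p.startswith("BG") for p in vset.all_probes())
        assert np.median(mes_rates) >= 0.9
        assert bg_hits == 0


class TestAverageSignatureScore:
    def test_single_probe_identity(self, toy_cohort):
        score = sig.average_signature_score(toy_cohort, ["A_at"])
        np.testing.assert_allclose(score.to_numpy(),
                                   toy_cohort.expression("A_at"))

    def test_two_probe_arithmetic(self):
        matrix = pd.DataFrame([[4.0, 6.0], [8.0, 10.0]],
                              index=["A_at", "B_at"], columns=["s1", "s2"])
        cohort = ExpressionCohort("c", matrix)
        score = sig.average_signature_score(cohort, ["A_at", "B_at"])
        np.testing.assert_allclose(score.to_numpy(), [6.0, 8.0])

    def test_probe_order_irrelevant(self, toy_cohort):
        a = sig.average_signature_score(toy_cohort, ["A_at", "B_at", "C_at"])
        b = sig.average_signature_score(toy_cohort, ["C_at", "A_at", "B_at"])
        pd.testing.assert_series_equal(a, b)

    def test_all_probes_missing_is_error(self, toy_cohort):
        with pytest.raises(ValueError):
            sig.average_signature_score(toy_cohort, ["Z_at"])


class TestPcaDistances:
    def _block_cohort(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        rows = {"TARGET_at": latent + 0.1 * rng.normal(size=n)}
        for i in range(5):
            rows[f"MES{i}_at"] = latent + 0.45 * rng.normal(size=n)
            rows[f"PN{i}_at"] = -latent + 0.45 * rng.normal(size=n)
        matrix = pd.DataFrame(rows).T
        matrix.columns = [f"s{j}" for j in range(n)]
        return ExpressionCohort("c", matrix)

    def test_duplicated_target_has_zero_distance(self):
        cohort = self._block_cohort()
        means, table = sig.pca_signature_distances(
            cohort, {"SELF": ["TARGET_at"], "MES": [f"MES{i}_at"
                                                    for i in range(5)]},
            "TARGET_at")
        assert table.loc["TARGET_at", "distance_to_target"] == 0.0

    def test_correlated_block_closer_than_anticorrelated(self):
        cohort = self._block_cohort(seed=3)
        means, _ = sig.pca_signature_distances(
            cohort,
            {"MES": [f"MES{i}_at" for i in range(5)],
             "PN": [f"PN{i}_at" for i in range(5)]},
            "TARGET_at")
        assert means["MES"] < means["PN"]

    def test_sample_order_invariance(self):
        cohort = self._block_cohort(seed=5)
        perm = np.random.default_rng(1).permutation(cohort.sample_ids)
        shuffled = ExpressionCohort("c2", cohort.matrix[perm])
        probes = {"MES": [f"MES{i}_at" for i in range(5)],
                  "PN": [f"PN{i}_at" for i in range(5)]}
        a, _ = sig.pca_signature_distances(cohort, probes, "TARGET_at")
        b, _ = sig.pca_signature_distances(shuffled, probes, "TARGET_at")
        assert a["MES"] == pytest.approx(b["MES"], abs=1e-9)
        assert a["PN"] == pytest.approx(b["PN"], abs=1e-9)


class TestDifferentialExpression:
    def test_cell_line_style_gates(self):
        rng = np.random.default_rng(8)
        n = 10
        up = np.r_[np.full(n, 8.0), np.full(n, 6.0)]       # 4-fold up
        mild = np.r_[np.full(n, 6.4), np.full(n, 6.0)]     # 1.3-fold, below gate
        flat = np.full(2 * n, 6.0)
        matrix = pd.DataFrame(
            {"UP_at": up, "MILD_at": mild, "FLAT_at": flat}).T
        matrix += rng.normal(0, 0.05, matrix.shape)
        matrix.columns = [f"s{j}" for j in range(2 * n)]
        mask_a = np.arange(2 * n) < n
        out = sig.differential_expression(matrix, mask_a, ~mask_a,
                                          fc_min=1.5, fdr_max=0.05)
        out = out.set_index("probe_id")
        assert out.loc["UP_at", "selected"]
        assert not out.loc["MILD_at", "selected"]
        assert not out.loc["FLAT_at", "selected"]
        assert out.loc["UP_at", "fold_change"] == pytest.approx(4.0, rel=0.1)
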