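"""Signature construction, MYCN correction, clustering and MNA separation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import wntpipe as wp
from wntpipe.errors import CoverageError, InputError
from wntpipe.simulate import simulate_cohort


def itr_frame(rows):
    """rows: list of (contrast, genes, directions)."""
    return pd.DataFrame(
        [
            {
                "regulator": "CTNNB1",
                "contrast": c,
                "overlap": len(g),
                "p": 0.01,
                "z": -3.0,
                "state": "inhibited",
                "contributing_genes": list(g),
                "contributing_directions": list(d),
            }
            for c, g, d in rows
        ]
    )


class TestBuildSignature:
    def test_single_contrast_support_excluded(self):
        res = itr_frame(
            [("c1", ["a", "b"], [-1, -1]), ("c2", ["b"], [-1]),
             ("c3", [], []), ("c4", [], []), ("c5", [], [])]
        )
        sig = wp.build_signature(res, "CTNNB1", min_contrasts=2)
        assert list(sig.genes["gene"]) == ["b"]

    def test_unanimous_direction_kept(self):
        res = itr_frame([("c1", ["g"], [-1]), ("c2", ["g"], [-1])])
        sig = wp.build_signature(res, "CTNNB1")
        assert sig.genes.set_index("gene").loc["g", "direction"] == -1
        assert sig.genes.set_index("gene").loc["g", "support"] == 2

    def test_direction_tie_is_unknown(self):
        res = itr_frame([("c1", ["g"], [1]), ("c2", ["g"], [-1])])
        sig = wp.build_signature(res, "CTNNB1")
        assert sig.genes.set_index("gene").loc["g", "direction"] == 0

    def test_contrast_order_invariance(self):
        rows = [("c1", ["a", "b"], [1, -1]), ("c2", ["a"], [1]),
                ("c3", ["b", "c"], [-1, 1])]
        a = wp.build_signature(itr_frame(rows), "CTNNB1")
        b = wp.build_signature(itr_frame(rows[::-1]), "CTNNB1")
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_matches_multiset_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        rows = []
        for c in range(5):
            genes = list(rng.choice(pool, rng.integers(5, 15), replace=False))
            rows.append((f"c{c}", genes, [1] * len(genes)))
        sig = wp.build_signature(itr_frame(rows), "CTNNB1", min_contrasts=2)
        counts = {}
        for _, genes, _ in rows:
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        expected = sorted(g for g, n in counts.items() if n >= 2)
        assert list(sig.genes["gene"]) == expected

    def test_missing_regulator_raises(self):
        with pytest.raises(InputError, match="absent"):
            wp.build_signature(itr_frame([("c1", [], []), ("c2", [], [])]),
                               "NOPE")


def _cohort_frame(n=500, seed=0):
    rng = np.random.default_rng(seed)
    amp = (rng.random(n) < 0.25).astype(int)
    mycn = np.where(amp == 1, rng.normal(11, 1, n), rng.normal(8, 1, n))
    samples = [f"S{i}" for i in range(n)]
    return (
        pd.Series(mycn, index=samples, name="mycn_expr"),
        pd.Series(amp, index=samples, name="mycn_amp"),
        rng,
    )


class TestMycnModel:
    def test_planted_slope_recovered(self):
        mycn, amp, rng = _cohort_frame(500, seed=1)
        y = 2.0 * mycn.to_numpy() + rng.normal(0, 0.5, 500)
        expr = pd.DataFrame([y], index=["probe1"], columns=mycn.index)
        model = wp.fit_mycn_model(expr, mycn, amp)
        assert 1.9 <= model.coefficients.loc["probe1", "b1"] <= 2.1

    def test_independent_row_has_null_partial_r2(self):
        mycn, amp, rng = _cohort_frame(500, seed=2)
        expr = pd.DataFrame(
            [rng.normal(0, 1, 500)], index=["p"], columns=mycn.index
        )
        model = wp.fit_mycn_model(expr, mycn, amp)
        assert model.coefficients.loc["p", "partial_r2"] < 0.02

    def test_identity_row_fits_exactly(self):
        mycn, amp, _ = _cohort_frame(200, seed=3)
        expr = pd.DataFrame([mycn.to_numpy()], index=["p"], columns=mycn.index)
        model = wp.fit_mycn_model(expr, mycn, amp)
        assert model.coefficients.loc["p", "b1"] == pytest.approx(1.0, abs=1e-8)
        assert model.coefficients.loc["p", "partial_r2"] == pytest.approx(
            1.0, abs=1e-8
        )

    def test_constant_row_zeroed(self):
        mycn, amp, _ = _cohort_frame(100, seed=4)
        expr = pd.DataFrame([np.full(100, 5.0)], index=["p"],
                            columns=mycn.index)
        model = wp.fit_mycn_model(expr, mycn, amp)
        row = model.coefficients.loc["p"]
        assert row["b1"] == 0 and row["b2"] == 0 and row["partial_r2"] == 0

    def test_single_class_rejected(self):
        mycn, amp, rng = _cohort_frame(100, seed=5)
        expr = pd.DataFrame([rng.normal(0, 1, 100)], index=["p"],
                            columns=mycn.index)
        with pytest.raises(InputError, match="amplification"):
            wp.fit_mycn_model(expr, mycn, amp * 0)


class TestCorrectMatrix:
    def _fitted(self, n=500, b1=1.5, seed=6):
        mycn, amp, rng = _cohort_frame(n, seed=seed)
        y = np.vstack(
            [
                b1 * mycn.to_numpy() + 0.8 * amp.to_numpy()
                + rng.normal(0, 0.5, n),
                rng.normal(0, 1, n),
            ]
        )
        expr = pd.DataFrame(y, index=["coupled", "null"], columns=mycn.index)
        model = wp.fit_mycn_model(expr, mycn, amp)
        return expr, model, mycn, amp

    def test_zero_coefficients_are_a_noop(self):
        expr, model, mycn, _ = self._fitted()
        model.coefficients["b1"] = 0.0
        corrected = wp.correct_matrix(expr, model, mycn)
        pd.testing.assert_frame_equal(corrected, expr)

    def test_corrected_rows_orthogonal_to_mycn(self):
        expr, model, mycn, amp = self._fitted()
        corrected = wp.correct_matrix(expr, model, mycn)
        # partial correlation with MYCN controlling for amplification
        X = np.column_stack([np.ones(len(mycn)), amp.to_numpy()])
        rm = mycn.to_numpy() - X @ np.linalg.lstsq(X, mycn.to_numpy(),
                                                   rcond=None)[0]
        y = corrected.loc["coupled"].to_numpy()
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r = np.corrcoef(rm, ry)[0, 1]
        assert abs(r) < 0.02

    def test_correction_is_idempotent(self):
        expr, model, mycn, amp = self._fitted()
        corrected = wp.correct_matrix(expr, model, mycn)
        refit = wp.fit_mycn_model(corrected, mycn, amp)
        assert np.abs(refit.coefficients["b1"]).max() < 1e-8
        again = wp.correct_matrix(corrected, refit, mycn)
        assert np.allclose(again.to_numpy(), corrected.to_numpy(), atol=1e-8)

    def test_amplification_effect_retained(self):
        expr, model, mycn, amp = self._fitted(b1=1.0, seed=8)
        corrected = wp.correct_matrix(expr, model, mycn)
        refit = wp.fit_mycn_model(corrected, mycn, amp)
        assert refit.coefficients.loc["coupled", "b2"] == pytest.approx(
            model.coefficients.loc["coupled", "b2"], abs=1e-8
        )

    def test_row_mismatch_rejected(self):
        expr, model, mycn, _ = self._fitted()
        with pytest.raises(InputError, match="different rows"):
            wp.correct_matrix(expr.iloc[:1], model, mycn)


class TestClusterSignature:
    def _planted(self, shift=3.0, n=60, n_probes=10, seed=9):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        truth = np.array([1] * (n // 3) + [0] * (n - n // 3))
        genes = [f"SIG{i:03d}" for i in range(n_probes)]
        dirs = [1 if i % 2 == 0 else -1 for i in range(n_probes)]
        sig = wp.Signature(
            regulator="CTNNB1",
            genes=pd.DataFrame({"gene": genes, "direction": dirs,
                                "support": 2}),
        )
        vals = np.vstack(
            [d * shift * truth + rng.normal(0, 1, n) for d in dirs]
        )
        expr = pd.DataFrame(vals, index=genes, columns=samples)
        return expr, sig, truth

    def test_planted_blocks_recovered_exactly(self):
        expr, sig, truth = self._planted(shift=3.0)
        groups = wp.cluster_signature(expr, sig)
        labels = (groups.labels == "signature_plus").astype(int)
        assert adjusted_rand_score(truth, labels) == 1.0
        # polarity: the shifted block scores higher
        assert (labels.to_numpy() == truth).all()

    def test_sample_permutation_invariance(self):
        expr, sig, _ = self._planted(seed=10)
        perm = expr.sample(frac=1.0, axis=1, random_state=1)
        a = wp.cluster_signature(expr, sig).labels
        b = wp.cluster_signature(perm, sig).labels
        assert a.sort_index().equals(b.sort_index())

    def test_bimodal_single_gene_splits_on_sign(self):
        # two probes of one gene, cleanly bimodal: groups = the sign split
        n = 40
        samples = [f"S{i}" for i in range(n)]
        vals = np.array([-2.0] * (n // 2) + [2.0] * (n // 2))
        expr = pd.DataFrame(
            [vals, vals], index=["G_p1", "G_p2"], columns=samples
        )
        probe_map = pd.Series(["G", "G"], index=["G_p1", "G_p2"])
        sig = wp.Signature(
            regulator="R",
            genes=pd.DataFrame({"gene": ["G"], "direction": [1],
                                "support": [2]}),
        )
        groups = wp.cluster_signature(expr, sig, probe_map=probe_map)
        assert (groups.labels[vals > 0] == "signature_plus").all()
        assert (groups.labels[vals < 0] == "signature_minus").all()

    def test_missing_probes_reported(self):
        expr, sig, _ = self._planted()
        with pytest.raises(CoverageError) as exc:
            wp.cluster_signature(expr.iloc[:1], sig)
        assert len(exc.value.missing) > 0

    def test_end_to_end_cohort_recovery(self):
        genes = pd.DataFrame(
            {"gene": [f"SIG{i:03d}" for i in range(20)],
             "direction": [1 if i % 2 else -1 for i in range(20)],
             "support": 2}
        )
        sig = wp.Signature(regulator="CTNNB1", genes=genes)
        aris = []
        for seed in range(5):
            expr, pmap, clin, truth = simulate_cohort(
                sig, n_samples=478, frac_amplified=0.2, activity_effect=1.0,
                noise_sd=0.5, seed=seed,
            )
            c = clin.set_index("sample")
            model = wp.fit_mycn_model(expr, c["mycn_expr"], c["mycn_amp"])
            corrected = wp.correct_matrix(expr, model, c["mycn_expr"])
            groups = wp.cluster_signature(corrected, sig, probe_map=pmap)
            aris.append(adjusted_rand_score(
                truth.activity, (groups.labels == "signature_plus").astype(int)
            ))
        assert np.mean(aris) >= 0.8


class TestMnaSeparation:
    def test_null_distributions_give_small_f(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(0, 1, 200),
                           index=[f"S{i}" for i in range(200)])
        amp = pd.Series(rng.integers(0, 2, 200), index=scores.index)
        F, p, _ = wp.mna_separation_test(scores, amp)
        assert p > 0.01

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(13)
        amp = pd.Series([0] * 200 + [1] * 200,
                        index=[f"S{i}" for i in range(400)])
        scores = pd.Series(
            rng.normal(0, 1, 400) + 2.0 * amp.to_numpy(), index=amp.index
        )
        F, p, _ = wp.mna_separation_test(scores, amp)
        assert p < 1e-10

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(14)
        amp = pd.Series([0] * 30 + [1] * 25, index=[f"S{i}" for i in range(55)])
        scores = pd.Series(rng.normal(0, 1, 55) + 0.4 * amp.to_numpy(),
                           index=amp.index)
        F, p, _ = wp.mna_separation_test(scores, amp)
        t, pt = stats.ttest_ind(scores[amp == 0], scores[amp == 1])
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_per_probe_bh_adjustment_properties(self):
        rng = np.random.default_rng(15)
        amp = pd.Series([0] * 50 + [1] * 50,
                        index=[f"S{i}" for i in range(100)])
        expr = pd.DataFrame(
            rng.normal(0, 1, (30, 100))
            + np.outer(np.linspace(0, 2, 30), amp.to_numpy()),
            index=[f"p{i}" for i in range(30)],
            columns=amp.index,
        )
        scores = pd.Series(expr.mean(axis=0), index=amp.index)
        _, _, table = wp.mna_separation_test(scores, amp, expr=expr)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        order = table.sort_values("p")
        assert order["p_adj"].is_monotonic_increasing

    def test_tiny_class_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=["a", "b", "c", "d"])
        amp = pd.Series([0, 0, 0, 1], index=scores.index)
        with pytest.raises(InputError, match=">= 2 samples"):
            wp.mna_separation_test(scores, amp)
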