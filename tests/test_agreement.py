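import numpy as np
import pytest

import earsleep as es
from earsleep.agreement import ConfusionMatrix, collapse_one_vs_rest


class TestAlign:
    def test_truncates_to_min_length(self):
        h1 = es.Hypnogram(["W"] * 900)
        h2 = es.Hypnogram(["N2"] * 910)
        assert len(es.align(h1, h2)) == 900

    def test_max_epochs_truncation(self):
        # 5 h 20 min of 30-s epochs = 640
        h1 = es.Hypnogram(["W"] * 900)
        h2 = es.Hypnogram(["W"] * 900)
        assert len(es.align(h1, h2, max_epochs=640)) == 640

    def test_identical_hypnograms_pair_equal(self):
        h = es.Hypnogram(["W", "N1", "N2"])
        assert all(a == b for a, b in es.align(h, h))

    def test_mismatched_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            es.align(es.Hypnogram(["W"]), es.Hypnogram(["W"], epoch_length=20))


class TestConfusion:
    def test_identical_pairs_fill_diagonal_cell(self):
        m = es.confusion([("N2", "N2")] * 10)
        assert m.counts[es.STAGES.index("N2"), es.STAGES.index("N2")] == 10
        assert m.total == 10

    def test_off_diagonal(self):
        m = es.confusion([("W", "N1"), ("N1", "W")])
        i, j = es.STAGES.index("W"), es.STAGES.index("N1")
        assert m.counts[i, j] == 1 and m.counts[j, i] == 1

    def test_concatenation_equals_matrix_sum(self, rng):
        stages = list(es.STAGES)
        p1 = [(rng.choice(stages), rng.choice(stages)) for _ in range(200)]
        p2 = [(rng.choice(stages), rng.choice(stages)) for _ in range(300)]
        summed = es.confusion(p1) + es.confusion(p2)
        concat = es.confusion(p1 + p2)
        np.testing.assert_array_equal(summed.counts, concat.counts)
        # and kappa of concatenated epochs equals kappa of summed matrices
        assert es.cohen_kappa(concat).kappa == pytest.approx(
            es.cohen_kappa(summed).kappa
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            es.confusion([("W", "N4")])


class TestCohenKappa:
    def test_perfect_diagonal_gives_one(self):
        m = ConfusionMatrix(np.diag([5, 10, 15, 20, 25, 30]))
        r = es.cohen_kappa(m)
        assert r.kappa == pytest.approx(1.0)
        assert r.po == pytest.approx(1.0)

    def test_rank_one_margins_give_zero(self):
        row = np.array([1, 2, 3, 4, 5, 6])
        m = ConfusionMatrix(np.outer(row, row))
        assert es.cohen_kappa(m).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_implementations(self, bundled):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        skm = pytest.importorskip("sklearn.metrics")
        for m in bundled.values():
            ours = es.cohen_kappa(m)
            ref = sm.cohens_kappa(m.counts)
            assert ours.kappa == pytest.approx(ref.kappa, abs=1e-12)
            assert ours.se == pytest.approx(np.sqrt(ref.var_kappa), rel=1e-9)
            # reconstruct the rating pairs and check sklearn agrees
            a, b = [], []
            for i, la in enumerate(m.labels):
                for j, lb in enumerate(m.labels):
                    a += [la] * m.counts[i, j]
                    b += [lb] * m.counts[i, j]
            assert ours.kappa == pytest.approx(
                skm.cohen_kappa_score(a, b), abs=1e-12
            )

    def test_permutation_invariance(self, bundled):
        m = bundled["fpz_eog_vs_ceegrid"]
        perm = [5, 3, 1, 0, 2, 4]
        mp = ConfusionMatrix(
            m.counts[np.ix_(perm, perm)], tuple(m.labels[i] for i in perm)
        )
        assert es.cohen_kappa(mp).kappa == pytest.approx(es.cohen_kappa(m).kappa)

    def test_se_scales_inverse_sqrt_counts(self, bundled):
        m = bundled["fpz_eog_test_retest"]
        se1 = es.cohen_kappa(m).se
        se4 = es.cohen_kappa(ConfusionMatrix(m.counts * 4, m.labels)).se
        assert se4 == pytest.approx(se1 / 2, rel=0.01)

    def test_degenerate_margins_rejected(self):
        m = ConfusionMatrix(np.diag([10, 0, 0, 0, 0, 0]))
        with pytest.raises(ZeroDivisionError):
            es.cohen_kappa(m)


class TestOneVsRest:
    def test_collapse_preserves_total(self, bundled):
        m = bundled["fpz_eog_test_retest"]
        for s in es.STAGES:
            assert collapse_one_vs_rest(m, s).total == m.total

    def test_perfect_diagonal_collapses_to_one(self):
        m = ConfusionMatrix(np.diag([5, 10, 15, 20, 25, 30]))
        for s in es.STAGES:
            assert es.one_vs_rest_kappa(m, s).kappa == pytest.approx(1.0)

    def test_published_per_stage_values(self, bundled):
        # N3 of the test-retest table and REM of the cEEGrid+EOG comparison
        r = es.one_vs_rest_kappa(bundled["fpz_eog_test_retest"], "N3")
        assert round(r.kappa, 2) == 0.90
        r = es.one_vs_rest_kappa(bundled["fpz_eog_vs_ceegrid_eog"], "REM")
        assert round(r.kappa, 2) == 0.83

    def test_absent_stage_rejected(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[1, 1] = 10
        with pytest.raises(ZeroDivisionError):
            es.one_vs_rest_kappa(ConfusionMatrix(counts), "N3")


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.2, "poor"), (0.0, "poor"), (0.1, "slight"), (0.20, "slight"),
            (0.37, "fair"), (0.40, "fair"), (0.46, "moderate"), (0.60, "moderate"),
            (0.67, "substantial"), (0.75, "substantial"), (0.80, "substantial"),
            (0.85, "almost perfect"), (0.90, "almost perfect"), (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert es.landis_koch_label(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.landis_koch_label(1.5)


class TestPairedT:
    def test_equal_vectors_give_half(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.4, 0.9, 8)
        with pytest.raises(ZeroDivisionError):
            es.paired_t_onetailed(a, a)  # zero-variance differences

    def test_exactly_centered_differences_give_p_half(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.4, 0.9, 50)
        noise = rng.normal(0, 0.01, 50)
        b = a + noise - noise.mean()  # mean difference exactly zero
        t, p = es.paired_t_onetailed(a, b)
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_p_shrinks_with_effect_size(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.4, 0.6, 10)
        noise = rng.normal(0, 0.02, 10)
        ps = []
        for shift in (0.01, 0.05, 0.2):
            _, p = es.paired_t_onetailed(a, a + shift + noise)
            ps.append(p)
        assert ps[0] > ps[1] > ps[2]

    def test_constant_difference_is_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            es.paired_t_onetailed([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])

    def test_direction_is_one_tailed_b_greater(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.4, 0.6, 10)
        b = a + 0.1 + rng.normal(0, 0.02, 10)
        _, p_fwd = es.paired_t_onetailed(a, b)
        _, p_rev = es.paired_t_onetailed(b, a)
        assert p_fwd < 0.05 < p_rev


def test_agreement_report_round_numbers():
    h1 = es.Hypnogram(["W"] * 50 + ["N2"] * 100 + ["N3"] * 50 + ["REM"] * 50)
    h2 = es.Hypnogram(["W"] * 45 + ["N1"] * 5 + ["N2"] * 100 + ["N3"] * 50 + ["REM"] * 50)
    rep = es.agreement_report(h1, h2)
    assert rep["n_epochs"] == 250
    assert 0 < rep["kappa"] <= 1
    assert rep["label"] in ("substantial", "almost perfect")
    assert set(rep["per_stage"]) <= {"W", "N1", "N2", "N3", "REM"}
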