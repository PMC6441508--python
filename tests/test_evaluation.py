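import numpy as np
import pytest
from scipy.stats import norm

from msisig.classifier import fit_centroids, score_samples
from msisig.containers import GeneSignature, ValueKind
from msisig.evaluation import (
    auc,
    compare_signatures,
    cross_validate,
    delong_ci,
    delong_paired_test,
    make_cv_plan,
)

from conftest import make_annotations, make_matrix

# Fixed 10+10 fixture whose DeLong quantities were computed once with the
# reference ROC implementation (pROC 1.19, roc.test/ci.auc, method
# "delong") and frozen.
PROC_LABELS = [1] * 10 + [0] * 10
PROC_A = [3.487247, 0.003228, 0.505707, 0.787707, 0.229327, 0.252720,
          1.948139, 1.083045, 1.352658, 3.389978, 0.356986, 2.716752,
          2.281452, 0.324021, 1.896067, 0.467681, -0.893801, -0.307328,
          -0.004822, 0.988164]
PROC_B = [1.239750, 1.105342, 1.705965, -0.987996, 1.672917, 0.584193,
          1.152280, 0.991745, -0.583053, 0.123936, -0.870851, 0.718711,
          0.110653, -0.078467, -0.420490, -0.562126, 0.997513, -1.105130,
          -0.142288, 0.314995]


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray(labels, dtype=bool)
    pos, neg = scores[is_pos], scores[~is_pos]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert auc([1.0] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_small_example(self):
        assert auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            assert auc(scores, labels) == brute_force_auc(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestDelongCi:
    def test_perfect_separation_degenerate(self):
        with pytest.warns(UserWarning, match="perfect separation"):
            roc = delong_ci([5, 6, 1, 2], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.delong_var == 0.0
        assert (roc.ci_low, roc.ci_high) == (1.0, 1.0)
        assert roc.degenerate

    def test_frozen_reference_values(self):
        roc = delong_ci(PROC_A, PROC_LABELS)
        assert roc.auc == pytest.approx(0.63, abs=1e-12)
        assert roc.delong_var == pytest.approx(0.017355555556, abs=1e-10)
        assert roc.ci_low == pytest.approx(0.371793392848, abs=1e-9)
        assert roc.ci_high == pytest.approx(0.888206607152, abs=1e-9)

    def test_variance_close_to_bootstrap(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30, dtype=bool)
        roc = delong_ci(scores, labels)
        boot = []
        pos, neg = scores[:30], scores[30:]
        for _ in range(10_000):
            bp = rng.choice(pos, 30)
            bn = rng.choice(neg, 30)
            boot.append(auc(np.concatenate([bp, bn]), labels))
        assert roc.delong_var == pytest.approx(
            np.var(boot), rel=0.2
        )

    def test_variance_scales_inversely_with_n(self, rng):
        ratios = []
        for _ in range(200):
            small = np.concatenate(
                [rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
            )
            big = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 60)])
            v_small = delong_ci(small, [1] * 30 + [0] * 30).delong_var
            v_big = delong_ci(big, [1] * 60 + [0] * 60).delong_var
            ratios.append(v_big / v_small)
        assert 0.35 <= np.median(ratios) <= 0.65


class TestDelongPairedTest:
    def test_identical_scores(self):
        a = [0.3, 0.7, 0.2, 0.9]
        _, _, z, p = delong_paired_test(a, a, [1, 1, 0, 0])
        assert z == 0.0 and p == 1.0

    def test_frozen_reference_values(self):
        auc_a, auc_b, z, p = delong_paired_test(PROC_A, PROC_B, PROC_LABELS)
        assert auc_a == pytest.approx(0.63)
        assert auc_b == pytest.approx(0.77)
        assert z == pytest.approx(-0.789786285167, abs=1e-9)
        assert p == pytest.approx(0.429652589941, abs=1e-9)

    def test_reversed_scores_extreme(self, rng):
        pos = rng.uniform(1, 2, 10)
        neg = rng.uniform(-2, -1, 10)
        a = np.concatenate([pos, neg])
        auc_a, auc_b, z, _ = delong_paired_test(a, -a, [1] * 10 + [0] * 10)
        assert auc_a == 1.0 and auc_b == 0.0
        assert z == np.inf  # zero paired variance at total separation

    def test_antisymmetry(self, rng):
        a = rng.normal(size=24)
        b = rng.normal(size=24)
        labels = [1] * 10 + [0] * 14
        _, _, z_ab, p_ab = delong_paired_test(a, b, labels)
        _, _, z_ba, p_ba = delong_paired_test(b, a, labels)
        assert z_ab == -z_ba
        assert p_ab == p_ba

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [1, 0])


class TestCvPlan:
    def test_partition_and_stratification(self):
        ann = make_annotations(
            ["MSI"] * 35 + ["MSS"] * 140,
            sample_ids=[f"s{i}" for i in range(175)],
        )
        plan = make_cv_plan(ann, k=10, seed=0)
        all_members = [s for fold in plan.folds for s in fold]
        assert sorted(all_members) == sorted(a.sample_id for a in ann)
        label_of = {a.sample_id: a.msi_label for a in ann}
        for fold in plan.folds:
            n_msi = sum(label_of[s] == "MSI" for s in fold)
            assert abs(n_msi - 3.5) <= 1
        assert len(plan.folds) == 10


class TestCrossValidate:
    def _separable(self, rng, n_genes=6, n=60):
        labels = ["MSI"] * 20 + ["MSS"] * 40
        shift = np.array([2.0, -2.0, 2.0, 2.0, -2.0, 2.0])
        values = rng.normal(size=(n_genes, n)) * 0.1
        values[:, :20] += shift[:, None]
        m = make_matrix(values, value_kind=ValueKind.LOG_INTENSITY)
        return m, make_annotations(labels)

    def test_deterministic(self, rng):
        m, ann = self._separable(rng)
        sig = GeneSignature(m.gene_ids)
        roc1, plan1 = cross_validate(m, ann, sig, k=5, seed=3)
        roc2, plan2 = cross_validate(m, ann, sig, k=5, seed=3)
        np.testing.assert_array_equal(roc1.scores, roc2.scores)
        assert plan1.folds == plan2.folds

    def test_separable_data_perfect_auc(self, rng):
        m, ann = self._separable(rng)
        with pytest.warns(UserWarning, match="perfect separation"):
            roc, _ = cross_validate(m, ann, GeneSignature(m.gene_ids),
                                    k=5, seed=1)
        assert roc.auc == 1.0

    def test_no_leakage(self, rng):
        """Out-of-fold scores must be reproducible from models refit on
        the training folds alone."""
        m, ann = self._separable(rng)
        sig = GeneSignature(m.gene_ids)
        roc, plan = cross_validate(m, ann, sig, k=5, seed=2)
        ann_by_id = {a.sample_id: a for a in ann}
        for fold in plan.folds:
            train_ids = [s for s in m.sample_ids if s not in set(fold)]
            model = fit_centroids(
                m.subset_samples(train_ids),
                [ann_by_id[s] for s in train_ids],
                sig,
            )
            expected = score_samples(
                m.subset_samples(fold), model, standardize_with="training"
            )
            got = roc.scores[[m.sample_ids.index(s) for s in fold]]
            np.testing.assert_allclose(got, expected.to_numpy())

    def test_lost_class_errors(self, rng):
        m, _ = self._separable(rng)
        ann = make_annotations(["MSI"] * 1 + ["MSS"] * 59)
        with pytest.warns(UserWarning):  # sklearn warns about the tiny class
            with pytest.raises(ValueError, match="smaller k"):
                cross_validate(m, ann, GeneSignature(m.gene_ids), k=10, seed=0)


class TestCompareSignatures:
    def test_reference_vs_itself_and_shared_plan(self, rng):
        labels = ["MSI"] * 25 + ["MSS"] * 50
        values = rng.normal(size=(12, 75))
        values[:6, :25] += 1.5
        m = make_matrix(values, value_kind=ValueKind.LOG_INTENSITY)
        ann = make_annotations(labels)
        ref = GeneSignature(m.gene_ids[:6], name="ref")
        dup = GeneSignature(m.gene_ids[:6], name="dup")
        noise = GeneSignature(m.gene_ids[6:], name="noise")
        absent = GeneSignature(["zz1", "zz2"], name="absent")
        table = compare_signatures(m, ann, [ref, dup, noise, absent],
                                   k=5, seed=0)
        assert table.loc["dup", "p_vs_reference"] == 1.0
        assert table.loc["ref", "adj_p_vs_reference"] == 1.0
        assert table.loc["noise", "auc"] < table.loc["ref", "auc"]
        assert table.loc["absent", "status"].startswith("failed")
        assert table.attrs["fold_plan"].folds  # one shared plan recorded


def test_delong_coverage_small_scale(rng):
    """95% DeLong CI covers the closed-form true AUC (Gaussian score
    model, AUC = Phi(delta/sqrt(2))) at roughly nominal rate."""
    delta = 1.0
    true_auc = norm.cdf(delta / np.sqrt(2))
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        scores = np.concatenate(
            [rng.normal(delta, 1, 30), rng.normal(0, 1, 30)]
        )
        roc = delong_ci(scores, [1] * 30 + [0] * 30)
        hits += roc.ci_low <= true_auc <= roc.ci_high
    assert 0.90 <= hits / n_rep <= 0.99
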