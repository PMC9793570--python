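"""Cohort statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from hepavol.stats import CohortRecord, icc_agreement, linreg_r2, pearson_r, \
    roc_auc, severity_report, spearman_rho, youden_cutoff
from hepavol.volumetry import VolumetryResult


def rank(v):
    """Midrank transform (oracle helper)."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def corr_oracle(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_rho([1, 2, 5, 9], [2, 4, 10, 18])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_small_case(self):
        # ranks of y: (3,1,2) vs (1,2,3): sum d^2 = 6 -> 1 - 36/24 = -0.5
        rho, p = spearman_rho([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)
        assert 0 < p <= 1

    def test_matches_midrank_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(corr_oracle(rank(x), rank(y)), abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        """For n = 4 the exact two-sided p matches full enumeration."""
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
        rho, p = spearman_rho(x, y)
        rx, ry = rank(x), rank(y)
        obs = abs(corr_oracle(rx, ry))
        count = sum(
            abs(corr_oracle(rx, ry[list(perm)])) >= obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        assert p == pytest.approx(count / 24)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestPearsonAndRegression:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert pearson_r(x, y) == pytest.approx(corr_oracle(x, y), abs=1e-12)

    def test_regression_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        y = 3 * x - 2 + rng.normal(scale=0.5, size=8)
        slope, intercept, r2, p = linreg_r2(x, y)
        X = np.column_stack([x, np.ones(8)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(pearson_r(x, y) ** 2, abs=1e-12)

    def test_exact_line_r2_one(self):
        x = np.arange(5.0)
        _, _, r2, _ = linreg_r2(x, 0.5 * x + 7)
        assert r2 == pytest.approx(1.0)


def icc_oracle(m):
    """ICC(2,1) from explicit ANOVA sums of squares."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((m - m.mean(1, keepdims=True) - m.mean(0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_raters(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_agreement(m) == pytest.approx(1.0)

    def test_offset_penalized_below_pearson(self):
        x = np.arange(6.0)
        m = np.column_stack([x, x + 10.0])
        assert icc_agreement(m) < pearson_r(x, x + 10.0)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.normal(50, 10, (6, 2))
            assert icc_agreement(m) == pytest.approx(icc_oracle(m), abs=1e-10)

    def test_matches_pingouin(self):
        """Cross-check the ICC variant against an independent implementation."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(6)
        m = rng.normal(100, 25, (8, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 2),
            "raters": np.tile(["a", "b"], 8),
            "scores": m.ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        sel = res["Type"].isin(["ICC2", "ICC(A,1)"])  # absolute agreement, single
        icc2_1 = float(res.loc[sel, "ICC"].iloc[0])
        assert icc_agreement(m) == pytest.approx(icc2_1, abs=1e-6)


def auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.ci_low <= res.auc <= res.ci_high

    def test_pair_enumeration_example(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=20)
        labels = (rng.random(20) > 0.5).astype(int)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(scores, 1 - labels).auc
        assert a1 == pytest.approx(1 - a2)

    def test_matches_mann_whitney_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = (rng.random(n) > 0.5).astype(int)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12)

    def test_bootstrap_ci_contains_auc(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
        labels = np.array([0] * 15 + [1] * 15)
        res = roc_auc(scores, labels, ci_method="bootstrap", seed=0)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_split(self):
        cutoff, sens, spec = youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert (cutoff, sens, spec) == (3.0, 100.0, 100.0)

    def test_degenerate_all_equal(self):
        cutoff, sens, spec = youden_cutoff([5, 5, 5, 5], [0, 1, 0, 1])
        assert sens + spec - 100.0 == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            scores = rng.normal(size=12)
            labels = np.array([0] * 6 + [1] * 6)
            rng.shuffle(labels)
            if labels.sum() in (0, 12):
                continue
            cutoff, sens, spec = youden_cutoff(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            best_j = max(
                np.mean(pos >= t) + np.mean(neg < t) - 1 for t in scores
            )
            assert (sens + spec) / 100.0 - 1 == pytest.approx(best_j, abs=1e-12)
            # the reported operating point reclassifies to itself
            assert np.mean(pos >= cutoff) * 100 == pytest.approx(sens)
            assert np.mean(neg < cutoff) * 100 == pytest.approx(spec)


def _records(lpdis, grades):
    out = []
    for i, (l, g) in enumerate(zip(lpdis, grades)):
        v = VolumetryResult(f"c{i}", 600.0, 6.0 * l, l)
        out.append(CohortRecord(f"c{i}", g, automated_volumetry=v,
                                reference_volumetry=v))
    return out


class TestSeverityReport:
    def test_separated_groups_auc_one(self):
        recs = _records([1, 2, 3, 10, 12, 14], [1, 1, 2, 3, 4, 5])
        rep = severity_report(recs)
        assert rep.loc["lpdi_pct", "auc"] == 1.0
        assert rep.loc["trauma_volume_ml", "auc"] == 1.0

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        lpdis = rng.uniform(1, 30, 60)
        grades = rng.permutation([1, 2, 3, 4, 5] * 12)
        rep = severity_report(_records(lpdis, grades))
        assert abs(rep.loc["lpdi_pct", "auc"] - 0.5) < 0.25

    def test_severity_grouping_boundary(self):
        assert CohortRecord("a", 2).severity_group == "low"
        assert CohortRecord("b", 3).severity_group == "high"
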