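"""Cohort-level statistics for trauma severity assessment.

Covers agreement between automated and reference volumetry (Pearson r,
ICC(2,1), ordinary least squares R^2), correlation of the severity indexes
with AAST grade (Spearman rank correlation), and low- vs high-grade
discrimination by ROC analysis with Youden-index optimal cutoffs.

Severity grouping follows the AAST convention for blunt hepatic trauma:
grades I-II are "low grade", grades III-V "high grade".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .volumetry import VolumetryResult

__all__ = [
    "CohortRecord",
    "RocResult",
    "spearman_rho",
    "pearson_r",
    "icc_agreement",
    "linreg_r2",
    "roc_auc",
    "youden_cutoff",
    "severity_report",
    "agreement_report",
    "volumetry_by_grade",
]

LOW_GRADES = frozenset({1, 2})
HIGH_GRADES = frozenset({3, 4, 5})


@dataclass
class CohortRecord:
    """One case: AAST grade plus reference and automated volumetry."""

    case_id: str
    aast_grade: int
    reference_volumetry: VolumetryResult | None = None
    automated_volumetry: VolumetryResult | None = None

    def __post_init__(self) -> None:
        if self.aast_grade not in range(1, 6):
            raise ValueError(f"AAST grade must be 1..5, got {self.aast_grade}")

    @property
    def severity_group(self) -> str:
        return "low" if self.aast_grade in LOW_GRADES else "high"


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float


def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all n! permutations of the y ranks in vectorized chunks and
    counts |rho_perm| >= |rho_obs|.
    """
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    count = 0
    total = 0
    it = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(it, 200_000))
        if not chunk:
            break
        perm = np.asarray(chunk, dtype=np.intp)
        rhos = (ry_c[perm] @ rx_c) / denom
        count += int(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)
    return count / total


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with two-sided p-value.

    Uses the exact permutation distribution for n <= 10 and the
    t-approximation above; constant input has no defined rank correlation
    and is rejected.
    """
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= 10:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def pearson_r(x, y) -> float:
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(sps.pearsonr(x, y).statistic)


def icc_agreement(measurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is an (n, 2) array of the same quantity measured by two
    raters (manual and automated).  Computed from the two-way ANOVA mean
    squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    All-identical data degenerates to exact agreement (ICC 1).
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("measurements must be an (n, 2) array")
    n, k = m.shape
    if n < 3:
        raise ValueError("need at least 3 cases")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def linreg_r2(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, r_squared, p) — p from the slope test."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for zero x-variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    """95% CI for the AUC by DeLong's method (placement-value variance)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n           # P(pos > neg) per positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m     # per negative
    if m > 1 and n > 1:
        var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    else:
        var = 0.0
    half = 1.959963984540054 * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _bootstrap_ci(scores, labels, seed: int, n_boot: int = 2000) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos_idx, len(pos_idx), replace=True),
            rng.choice(neg_idx, len(neg_idx), replace=True),
        ])
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc_auc(scores, labels, ci_method: str = "delong", seed: int = 0) -> RocResult:
    """AUC (= Mann-Whitney probability, ties counted 1/2) with 95% CI.

    ``ci_method`` is "delong" (default, deterministic) or "bootstrap"
    (stratified, 2000 replicates, seeded).  The Youden operating point is
    filled in from :func:`youden_cutoff`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auc = float(roc_auc_score(labels, scores))
    if ci_method == "delong":
        lo, hi = _delong_ci(scores, labels, auc)
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(scores, labels, seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cutoff, sens, spec = youden_cutoff(scores, labels)
    return RocResult(auc, lo, hi, cutoff, sens, spec)


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Optimal cutoff by Youden's index (J = sensitivity + specificity - 1).

    Candidate thresholds are the observed score values; a case is called
    positive when score >= threshold.  Ties in J are broken toward the
    smaller cutoff (the more sensitive operating point).  Returns
    (cutoff, sensitivity_pct, specificity_pct).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    candidates = np.unique(scores)
    best = None
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    assert best is not None
    _, cutoff, sens, spec = best
    return cutoff, 100.0 * sens, 100.0 * spec


def _require_automated(cohort: list[CohortRecord]) -> None:
    missing = [r.case_id for r in cohort if r.automated_volumetry is None]
    if missing:
        raise ValueError(f"cases without automated volumetry: {missing[:5]}")


def severity_report(cohort: list[CohortRecord], ci_method: str = "delong",
                    seed: int = 0) -> pd.DataFrame:
    """Low- vs high-grade discrimination by trauma volume and LPDI.

    Emits one row per index with AUC, 95% CI, Youden cutoff and its
    operating point, plus the Spearman rho (and p) of the index against
    AAST grade.  Requires at least 2 cases in each severity group.
    """
    _require_automated(cohort)
    grades = np.array([r.aast_grade for r in cohort])
    labels = np.array([1 if r.severity_group == "high" else 0 for r in cohort])
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 cases in each severity group")
    rows = []
    for name, scores in [
        ("trauma_volume_ml", np.array([r.automated_volumetry.trauma_volume_ml for r in cohort])),
        ("lpdi_pct", np.array([r.automated_volumetry.lpdi_pct for r in cohort])),
    ]:
        roc = roc_auc(scores, labels, ci_method=ci_method, seed=seed)
        rho, p = spearman_rho(scores, grades)
        rows.append({
            "index": name,
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "sensitivity_pct": roc.sensitivity_pct,
            "specificity_pct": roc.specificity_pct,
            "cutoff": roc.cutoff,
            "spearman_rho_vs_grade": rho, "spearman_p": p,
        })
    return pd.DataFrame(rows).set_index("index")


def agreement_report(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Reference-vs-automated agreement for liver volume, trauma volume, LPDI."""
    _require_automated(cohort)
    if any(r.reference_volumetry is None for r in cohort):
        raise ValueError("agreement report requires reference volumetry on every case")
    rows = []
    for name, attr in [("liver_volume_ml", "liver_volume_ml"),
                       ("trauma_volume_ml", "trauma_volume_ml"),
                       ("lpdi_pct", "lpdi_pct")]:
        ref = np.array([getattr(r.reference_volumetry, attr) for r in cohort])
        auto = np.array([getattr(r.automated_volumetry, attr) for r in cohort])
        slope, intercept, r2, p = linreg_r2(ref, auto)
        rows.append({
            "index": name,
            "pearson_r": pearson_r(ref, auto),
            "icc": icc_agreement(np.column_stack([ref, auto])),
            "r_squared": r2, "slope": slope, "intercept": intercept, "p": p,
        })
    return pd.DataFrame(rows).set_index("index")


def volumetry_by_grade(cohort: list[CohortRecord]) -> pd.DataFrame:
    """Automated volumetry stratified by AAST grade.

    Reports both mean (SD) and median (IQR) per grade for liver volume,
    trauma volume and LPDI.
    """
    _require_automated(cohort)
    df = pd.DataFrame({
        "grade": [r.aast_grade for r in cohort],
        "liver_volume_ml": [r.automated_volumetry.liver_volume_ml for r in cohort],
        "trauma_volume_ml": [r.automated_volumetry.trauma_volume_ml for r in cohort],
        "lpdi_pct": [r.automated_volumetry.lpdi_pct for r in cohort],
    })
    out = []
    for grade, sub in df.groupby("grade", sort=True):
        row: dict = {"grade": grade, "n": len(sub)}
        for c in ["liver_volume_ml", "trauma_volume_ml", "lpdi_pct"]:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
            row[f"{c}_median"] = float(sub[c].median())
            q1, q3 = sub[c].quantile([0.25, 0.75])
            row[f"{c}_iqr"] = float(q3 - q1)
        out.append(row)
    return pd.DataFrame(out).set_index("grade")
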