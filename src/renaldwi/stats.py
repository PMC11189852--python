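"""Clinical and cohort-level statistics.

Covers the statistical layer of the analysis: the 2009 CKD-EPI creatinine
eGFR equation, two-group comparisons (Student t for normally distributed
clinical variables, Mann-Whitney U for MRI parameters with exact
enumeration at small n, Pearson chi-square for sex), Spearman rank
correlation, inter-observer ICC(2,1), ROC analysis with Youden-index
cutoffs, and multivariable linear score models whose fitted scores feed
back into the ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm

from .errors import RenalDwiError

__all__ = [
    "egfr_ckd_epi",
    "creatinine_for_egfr",
    "GroupTestResult",
    "group_compare",
    "significance_stars",
    "spearman",
    "icc_two_observer",
    "RocResult",
    "roc",
    "ScoreModel",
    "fit_score_model",
    "auc_band",
]

MW_EXACT_MAX_N = 12
SPEARMAN_EXACT_MAX_N = 9


# ---------------------------------------------------------------- eGFR

def egfr_ckd_epi(scr: float, age: float, sex: str, black: bool = False) -> float:
    """2009 CKD-EPI creatinine eGFR in mL/min/1.73 m^2.

    scr in mg/dL; sex is 'F' or 'M'.  The race coefficient defaults to
    off (kept only for formula completeness).
    """
    if scr <= 0:
        raise RenalDwiError("serum creatinine must be positive")
    if not 18 <= age <= 110:
        raise RenalDwiError("age must lie in [18, 110] years")
    sex = sex.upper()
    if sex not in ("F", "M"):
        raise RenalDwiError("sex must be 'F' or 'M'")
    kappa = 0.7 if sex == "F" else 0.9
    alpha = -0.329 if sex == "F" else -0.411
    ratio = scr / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
    if sex == "F":
        egfr *= 1.018
    if black:
        egfr *= 1.159
    return float(egfr)


def creatinine_for_egfr(egfr: float, age: float, sex: str, black: bool = False) -> float:
    """Invert the CKD-EPI equation: creatinine (mg/dL) giving a target eGFR.

    The equation is piecewise power-law in scr and strictly decreasing, so
    the inverse is closed-form on each branch.
    """
    if egfr <= 0:
        raise RenalDwiError("target eGFR must be positive")
    sex = sex.upper()
    kappa = 0.7 if sex == "F" else 0.9
    alpha = -0.329 if sex == "F" else -0.411
    base = 141.0 * 0.993**age * (1.018 if sex == "F" else 1.0) * (1.159 if black else 1.0)
    r = egfr / base
    if r >= 1.0:
        ratio = r ** (1.0 / alpha)        # scr <= kappa branch (alpha < 0)
    else:
        ratio = r ** (1.0 / -1.209)       # scr > kappa branch
    return float(kappa * ratio)


# ----------------------------------------------------- group comparison

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of the first sample, with average ranks for ties."""
    combined = np.concatenate([x, y])
    ranks = ss.rankdata(combined)
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group-label assignments.

    Two-sidedness is measured as deviation of U from its null mean
    n1*n2/2, which handles ties correctly (average ranks throughout).
    """
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = ss.rankdata(combined)
    mu = n1 * n2 / 2.0
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def group_compare(x, y, kind: str = "mannwhitney") -> GroupTestResult:
    """Two-group comparison.

    ``mannwhitney`` (MRI parameters): exact enumeration when the combined
    n is <= 12, else the tie-corrected normal approximation.  ``t``
    (age, eGFR): two-sided pooled-variance Student t.  ``chi2`` (sex):
    Pearson chi-square on the 2x2 count table [x, y] without continuity
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise RenalDwiError("both groups must be non-empty")
    if kind == "mannwhitney":
        if x.size + y.size <= MW_EXACT_MAX_N:
            u, p = _mann_whitney_exact(x, y)
            return GroupTestResult("mannwhitney_exact", u, p)
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return GroupTestResult("mannwhitney_asymptotic", float(res.statistic), float(res.pvalue))
    if kind == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise RenalDwiError("t-test on constant data")
        res = ss.ttest_ind(x, y, equal_var=True)
        return GroupTestResult("t", float(res.statistic), float(res.pvalue))
    if kind == "chi2":
        table = np.array([x, y], float)
        if table.shape != (2, 2):
            raise RenalDwiError("chi2 expects two 2-element count vectors")
        if np.all(table == table[0, 0]) or table.sum() == 0:
            return GroupTestResult("chi2", 0.0, 1.0)
        stat, p, _, _ = ss.chi2_contingency(table, correction=False)
        return GroupTestResult("chi2", float(stat), float(p))
    raise RenalDwiError(f"unknown test kind {kind!r}")


# ------------------------------------------------------------- spearman

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p value: exact permutation enumeration for n <= 9 (valid under ties),
    otherwise the usual t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise RenalDwiError("spearman needs paired vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RenalDwiError("spearman is undefined for a constant vector")
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-15, 1 - rho**2))
        p = float(2 * ss.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


# ------------------------------------------------------------------ ICC

def icc_two_observer(meas1, meas2) -> tuple[float, str]:
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1).

    Returns the coefficient and its agreement band: poor (< 0.6),
    fair (0.6-0.8), good (> 0.8).
    """
    m1 = np.asarray(meas1, float)
    m2 = np.asarray(meas2, float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise RenalDwiError("paired 1-D measurement vectors required")
    if m1.size < 5:
        raise RenalDwiError("ICC needs at least 5 paired measurements")
    if not (np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))):
        raise RenalDwiError("ICC requires finite measurements")
    data = np.column_stack([m1, m2])
    if np.ptp(data) == 0:
        raise RenalDwiError("ICC undefined for zero total variance")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc = float(icc)
    band = "poor" if icc < 0.6 else ("fair" if icc <= 0.8 else "good")
    return icc, band


# ------------------------------------------------------------------ ROC

@dataclass(frozen=True)
class RocResult:
    """Oriented ROC summary for one marker or model score."""

    auc: float
    orientation: str        # 'higher' or 'lower': which direction flags disease
    cutoff: float           # in marker units, at the observed value
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _rank_auc(marker: np.ndarray, label: np.ndarray) -> float:
    """Tie-adjusted Mann-Whitney AUC: P(X_pos > X_neg) + 0.5 P(tie)."""
    pos = marker[label == 1]
    neg = marker[label == 0]
    ranks = ss.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc(marker, label) -> RocResult:
    """ROC analysis of one continuous marker against 0/1 group labels.

    AUC is the rank (Mann-Whitney) statistic; if the raw AUC is below 0.5
    the marker is re-oriented (lower values flag disease) and the flip
    recorded.  The cutoff maximizes the Youden index over all observed
    marker values, ties broken toward higher specificity, and is reported
    as the observed value in original units.
    """
    marker = np.asarray(marker, float)
    label = np.asarray(label, int)
    if marker.size != label.size:
        raise RenalDwiError("marker and label lengths differ")
    if not (np.any(label == 0) and np.any(label == 1)):
        raise RenalDwiError("both classes must be present")
    if not np.all(np.isfinite(marker)):
        raise RenalDwiError("marker contains non-finite values")
    raw_auc = _rank_auc(marker, label)
    if raw_auc < 0.5:
        orientation = "lower"
        oriented = -marker
        auc = 1.0 - raw_auc
    else:
        orientation = "higher"
        oriented = marker
        auc = raw_auc
    pos = oriented[label == 1]
    neg = oriented[label == 0]
    best = None   # (j, specificity, cutoff_oriented)
    for thr in np.unique(oriented):
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    cutoff = -thr if orientation == "lower" else thr
    return RocResult(
        auc=auc, orientation=orientation, cutoff=float(cutoff),
        sensitivity=sens, specificity=spec,
    )


def auc_band(auc: float) -> str:
    """Diagnostic-performance band for an AUC value."""
    if auc < 0.6:
        return "poor"
    if auc < 0.7:
        return "acceptable"
    if auc < 0.8:
        return "moderate"
    if auc < 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------- score model

MAX_PREDICTORS = 3
CONDITION_LIMIT = 1e8


@dataclass
class ScoreModel:
    """Multivariable linear score: OLS of the 0/1 group label on predictors.

    For ROC purposes only the ordering of fitted scores matters, so a
    linear probability model and logistic regression give monotonically
    related diagnostics; logistic is available via ``method='logistic'``.
    """

    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    method: str
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame.loc[:, list(self.predictors)].to_numpy(float)
        return self.intercept + x @ self.coefficients


def fit_score_model(
    frame: pd.DataFrame,
    predictors: list[str],
    label_column: str = "label",
    method: str = "linear",
) -> ScoreModel:
    """Fit the diagnostic score model on a per-subject table.

    At most 3 predictors; missing or non-finite values and near-collinear
    designs (condition number above 1e8) are rejected.
    """
    if not 1 <= len(predictors) <= MAX_PREDICTORS:
        raise RenalDwiError(f"between 1 and {MAX_PREDICTORS} predictors required")
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise RenalDwiError(f"predictors not in table: {missing}")
    x = frame.loc[:, predictors].to_numpy(float)
    y = frame[label_column].to_numpy(float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise RenalDwiError("predictors and label must be finite for all records")
    design = sm.add_constant(x, has_constant="add")
    cond = float(np.linalg.cond(design / np.abs(design).max(axis=0)))
    if cond > CONDITION_LIMIT:
        raise RenalDwiError(f"collinear predictors (condition number {cond:.2e})")
    if method == "linear":
        fit = sm.OLS(y, design).fit()
        params = np.asarray(fit.params)
    elif method == "logistic":
        fit = sm.Logit(y, design).fit(disp=0)
        params = np.asarray(fit.params)
    else:
        raise RenalDwiError(f"unknown method {method!r}")
    scores = design @ params
    return ScoreModel(
        predictors=tuple(predictors),
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        method=method,
        scores=np.asarray(scores, float),
        provenance={"n": int(y.size), "condition_number": cond, "label": label_column},
    )
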