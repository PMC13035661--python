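"""Prognostic evaluation of morphometric markers against a binary outcome.

Markers are evaluated univariately against adverse aortic remodeling:
ROC curve and AUC with a DeLong 95% confidence interval, the Youden
operating point with sensitivity / specificity / predictive values, the
two-sample Kolmogorov–Smirnov distance between the event and event-free
marker distributions, normality-guarded group-difference tests, and a
univariate logistic likelihood-ratio test.

Conventions: a subject is called positive when the marker value is at
or above the threshold (all markers here are adverse when large; a
direction flag covers the opposite case), and the AUC is computed by
trapezoid over the empirical ROC, which equals the midrank
Mann–Whitney statistic with ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import PerfectSeparationError

DEFAULT_CI_LEVEL = 0.95

#: Group size at or above which the t-test is used without a normality check.
NORMALITY_EXEMPT_N = 30


@dataclass
class RocResult:
    """Empirical ROC curve plus AUC and (optionally) CI and operating point.

    ``thresholds`` are the observed marker values in increasing order;
    ``sensitivity``/``specificity`` give the confusion rates of the rule
    "positive if value >= threshold" at each of them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float = None
    auc_ci_high: float = None
    youden_threshold: float = None
    se: float = None
    sp: float = None
    ppv: float = None
    npv: float = None
    larger_is_positive: bool = True
    values: np.ndarray = field(default=None, repr=False)
    outcomes: np.ndarray = field(default=None, repr=False)


def _check_two_classes(values, outcomes):
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes)
    if values.shape != outcomes.shape or values.ndim != 1:
        raise ValueError("values and outcomes must be equal-length 1D arrays")
    if not np.all(np.isin(outcomes, [0, 1])):
        raise ValueError("outcomes must be binary 0/1")
    outcomes = outcomes.astype(int)
    if outcomes.min() == outcomes.max():
        raise ValueError("both outcome classes must be present")
    if not np.all(np.isfinite(values)):
        raise ValueError("marker values must be finite")
    return values, outcomes


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(values, outcomes, larger_is_positive: bool = True) -> RocResult:
    """Empirical ROC and trapezoid AUC of one marker.

    The ROC is built from every observed marker value as a threshold
    with the rule "positive if value >= threshold"; the trapezoid area
    equals the midrank Mann–Whitney statistic U/(n1·n0) with ties
    counted 1/2.

    Parameters
    ----------
    values, outcomes : array-like
        Marker values and binary outcomes (1 = event).
    larger_is_positive : bool
        Set False for markers where smaller values indicate events; the
        ROC is then computed on the negated marker and thresholds are
        reported on the original scale.
    """
    values, outcomes = _check_two_classes(values, outcomes)
    work = values if larger_is_positive else -values

    thr = np.unique(work)  # ascending
    pos = work[outcomes == 1]
    neg = work[outcomes == 0]
    n1, n0 = len(pos), len(neg)
    # rule: positive if value >= threshold
    se = (pos[None, :] >= thr[:, None]).mean(axis=1)
    sp = (neg[None, :] < thr[:, None]).mean(axis=1)

    # trapezoid over the full curve including the (0,0) / (1,1) corners
    fpr = np.concatenate([[1.0], 1.0 - sp, [0.0]])
    tpr = np.concatenate([[1.0], se, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    out_thr = thr if larger_is_positive else -thr[::-1]
    out_se = se if larger_is_positive else se[::-1]
    out_sp = sp if larger_is_positive else sp[::-1]
    return RocResult(
        thresholds=out_thr,
        sensitivity=out_se,
        specificity=out_sp,
        auc=auc,
        larger_is_positive=larger_is_positive,
        values=values,
        outcomes=outcomes,
    )


def mannwhitney_auc(values, outcomes) -> float:
    """AUC via midrank Mann–Whitney U (ties 1/2); equals the trapezoid AUC."""
    values, outcomes = _check_two_classes(values, outcomes)
    ranks = stats.rankdata(values)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    u = ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_confidence_interval(
    values, outcomes, level: float = DEFAULT_CI_LEVEL, larger_is_positive: bool = True
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1].

    The variance is estimated from the event and non-event placement
    values (structural components); the Wald interval is formed on the
    AUC scale.  When every marker value is tied the variance degenerates
    and the interval collapses to (auc, auc) with a warning.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    values, outcomes = _check_two_classes(values, outcomes)
    if (outcomes == 1).sum() < 2 or (outcomes == 0).sum() < 2:
        raise ValueError("need >= 2 subjects per class for a CI")
    work = values if larger_is_positive else -values
    x = work[outcomes == 1]
    y = work[outcomes == 0]
    psi = (x[:, None] > y[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # placement of each event among non-events
    v01 = psi.mean(axis=0)
    var = v10.var(ddof=1) / len(x) + v01.var(ddof=1) / len(y)
    if var <= 0:
        # all values tied, or perfect separation: no placement variation
        warnings.warn("degenerate DeLong variance; interval collapses to the AUC")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def bootstrap_auc_ci(
    values,
    outcomes,
    level: float = DEFAULT_CI_LEVEL,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded stratified percentile-bootstrap CI for the AUC (alternative
    to the analytic DeLong interval)."""
    values, outcomes = _check_two_classes(values, outcomes)
    rng = np.random.default_rng(seed)
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(pos, size=len(pos), replace=True)
        yb = rng.choice(neg, size=len(neg), replace=True)
        gt = (xb[:, None] > yb[None, :]).mean()
        eq = (xb[:, None] == yb[None, :]).mean()
        aucs[b] = gt + 0.5 * eq
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def youden_operating_point(roc: RocResult) -> RocResult:
    """Annotate a ROC with the Youden-index operating point.

    The threshold maximises J = Se + Sp - 1; ties break toward the
    lowest threshold, which keeps sensitivity maximal at equal J.  PPV
    and NPV come from the 2x2 table at that threshold on the same
    cohort; an undefined predictive value (empty cell) is NaN.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    i = int(np.argmax(j))  # thresholds ascending -> first max = lowest
    thr = float(roc.thresholds[i])
    se = float(roc.sensitivity[i])
    sp = float(roc.specificity[i])
    if roc.values is None or roc.outcomes is None:
        raise ValueError("RocResult lacks the cohort needed for PPV/NPV")
    if roc.larger_is_positive:
        pred = roc.values >= thr
    else:
        pred = roc.values <= thr
    tp = int(np.sum(pred & (roc.outcomes == 1)))
    fp = int(np.sum(pred & (roc.outcomes == 0)))
    tn = int(np.sum(~pred & (roc.outcomes == 0)))
    fn = int(np.sum(~pred & (roc.outcomes == 1)))
    roc.youden_threshold = thr
    roc.se = se
    roc.sp = sp
    roc.ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    roc.npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return roc


# ---------------------------------------------------------------------------
# distribution distance and group tests
# ---------------------------------------------------------------------------

def ks_statistic(values_event, values_nonevent) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: the maximal absolute ECDF
    difference over the pooled sample points."""
    a = np.asarray(values_event, dtype=float)
    b = np.asarray(values_nonevent, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class GroupTestResult:
    statistic: float
    pvalue: float
    test: str


def group_difference_test(
    a,
    b,
    paired: bool = False,
    force_nonparametric: bool = False,
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """Two-group difference test with a normality guard.

    Uses Student's t (paired or two-sample) when both groups have
    n >= 30 or a Shapiro–Wilk test finds no evidence against normality;
    otherwise Wilcoxon signed-rank (paired) or Mann–Whitney U.  The test
    actually applied is reported in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal group lengths")

    use_t = not force_nonparametric
    if use_t and (min(a.size, b.size) < NORMALITY_EXEMPT_N):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if paired:
                diff = a - b
                normal = (
                    np.allclose(diff, diff[0])  # constant diffs: Shapiro undefined
                    or stats.shapiro(diff).pvalue > alpha_normality
                )
            else:
                normal = (
                    stats.shapiro(a).pvalue > alpha_normality
                    and stats.shapiro(b).pvalue > alpha_normality
                )
        use_t = normal

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_t:
            if paired:
                res = stats.ttest_rel(a, b)
                name = "paired t"
            else:
                res = stats.ttest_ind(a, b)
                name = "two-sample t"
        else:
            if paired:
                res = stats.wilcoxon(a, b)
                name = "wilcoxon"
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                name = "mann-whitney"
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(p):  # identical groups give a 0/0 t statistic
        stat, p = 0.0, 1.0
    return GroupTestResult(statistic=stat, pvalue=p, test=name)


# ---------------------------------------------------------------------------
# univariate logistic likelihood-ratio test
# ---------------------------------------------------------------------------

def _logistic_irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 100):
    """Fit logit(P(y=1)) = b0 + b1 x by iteratively reweighted least
    squares; returns (beta, loglik).  Divergence of the coefficients is
    treated as (quasi-)separation."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(maxiter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        if np.linalg.norm(grad) < tol:
            break
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise PerfectSeparationError("singular information matrix")
        beta = beta + delta
        if np.abs(beta[1]) * (x.max() - x.min() + 1e-300) > 700:
            raise PerfectSeparationError("diverging logistic coefficients")
    eta = np.clip(X @ beta, -700, 700)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-300
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return beta, ll


def likelihood_ratio_test(marker, outcomes) -> tuple[float, float]:
    """Univariate logistic likelihood-ratio test of one marker.

    LR = 2 (loglik(marker model) - loglik(intercept-only)); p from a
    chi-square with 1 df.  Perfect separation (the marker splits the
    classes without overlap) makes the statistic unbounded and raises
    :class:`PerfectSeparationError`.
    """
    values, y = _check_two_classes(marker, outcomes)
    pos = values[y == 1]
    neg = values[y == 0]
    if pos.min() > neg.max() or pos.max() < neg.min():
        raise PerfectSeparationError(
            "marker perfectly separates the outcome groups"
        )
    # standardise for IRLS conditioning; LR is invariant to affine maps
    scale = values.std()
    x = (values - values.mean()) / (scale if scale > 0 else 1.0)
    _, ll1 = _logistic_irls(x, y.astype(float))
    p0 = y.mean()
    ll0 = float(y.sum() * np.log(p0) + (len(y) - y.sum()) * np.log(1 - p0))
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return lr, p


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

def evaluate_marker(
    values,
    outcomes,
    level: float = DEFAULT_CI_LEVEL,
    larger_is_positive: bool = True,
) -> dict:
    """Full univariate report for one marker (AUC, CI, Youden point,
    KS distance, group-difference and likelihood-ratio tests)."""
    values, outcomes = _check_two_classes(values, outcomes)
    roc = roc_auc(values, outcomes, larger_is_positive)
    roc.auc_ci_low, roc.auc_ci_high = auc_confidence_interval(
        values, outcomes, level, larger_is_positive
    )
    youden_operating_point(roc)
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    group = group_difference_test(pos, neg)
    try:
        lr, lr_p = likelihood_ratio_test(values, outcomes)
    except PerfectSeparationError:
        lr, lr_p = float("inf"), 0.0
    return {
        "auc": roc.auc,
        "auc_ci_low": roc.auc_ci_low,
        "auc_ci_high": roc.auc_ci_high,
        "threshold": roc.youden_threshold,
        "sensitivity": roc.se,
        "specificity": roc.sp,
        "ppv": roc.ppv,
        "pnv": roc.npv,  # "PNV" kept as the report label for the NPV
        "ks": ks_statistic(pos, neg),
        "group_test": group.test,
        "group_p": group.pvalue,
        "lr_statistic": lr,
        "lr_p": lr_p,
        "n_event": int((outcomes == 1).sum()),
        "n_nonevent": int((outcomes == 0).sum()),
    }
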