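"""Prognostic-evaluation statistics for ordinal clinical scores.

Everything needed to compare two clot burden schemes against binary stroke
outcomes: outcome dichotomization, tie-corrected Spearman rank correlation,
empirical ROC curves with the Mann-Whitney AUC and DeLong variance, the
paired DeLong test for correlated AUCs, Youden-index cutoff selection,
intraclass correlation ICC(2,1) for inter-rater reliability, the Wilcoxon
rank-sum and Fisher exact tests, score-by-outcome contingency tables, and a
Hanley-McNeil post-hoc power approximation for an AUC difference.

Orientation convention: a LOW score predicts the adverse outcome, so ROC
operating points use the positivity rule ``score <= c`` and the AUC is
``P(score_pos < score_neg) + 0.5 * P(score_pos = score_neg)``.

The rank statistics are computed on midranks throughout; scipy is used only
for probability distributions (t, normal, F, hypergeometric), never for the
statistics themselves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutcomeLabels",
    "CorrelationResult",
    "RocResult",
    "PairedAucComparison",
    "YoudenResult",
    "IccResult",
    "ConstantInputError",
    "DegenerateLabelsError",
    "ZeroVarianceError",
    "dichotomize",
    "spearman",
    "roc",
    "delong_paired",
    "youden",
    "icc",
    "icc_band",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "stratified_spearman",
    "score_outcome_table",
    "auc_power_posthoc",
]


class ConstantInputError(ValueError):
    """A correlation was requested on a constant vector."""


class DegenerateLabelsError(ValueError):
    """ROC analysis requested with only one outcome class present."""


class ZeroVarianceError(ValueError):
    """A paired AUC contrast has zero estimated variance but nonzero delta."""


# ---------------------------------------------------------------------------
# outcome labels and dichotomization


@dataclass(frozen=True)
class OutcomeLabels:
    """Binary outcome vector with its clinical meaning.

    ``positive_meaning`` is one of ``mortality`` (mRS90 = 6), ``disability``
    (mRS90 >= 2) or ``severity`` (NIHSS >= 15).
    """

    labels: np.ndarray
    positive_meaning: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=int)
        if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be a 1-D vector of 0/1")
        object.__setattr__(self, "labels", arr)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def dichotomize(mrs90: int, nihss: int) -> tuple[int, int, int]:
    """Map (mRS90, NIHSS) to the (mortality, disability, severity) triple.

    mortality: death at 90 days (mRS90 = 6); disability: any dependence or
    worse at 90 days (mRS90 >= 2); severity: severe stroke at admission
    (NIHSS >= 15).
    """
    mrs90 = int(mrs90)
    nihss = int(nihss)
    if not 0 <= mrs90 <= 6:
        raise ValueError(f"mRS90 must be in 0..6, got {mrs90}")
    if not 0 <= nihss <= 42:
        raise ValueError(f"NIHSS must be in 0..42, got {nihss}")
    return int(mrs90 == 6), int(mrs90 >= 2), int(nihss >= 15)


# ---------------------------------------------------------------------------
# Spearman rank correlation


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "t-approximation" or "permutation"


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


# exact permutation is used up to this n (8! = 40320 orderings)
_EXACT_PERM_MAX_N = 8
_MC_PERMUTATIONS = 20000


def spearman(x, y, *, rng_seed: int = 0) -> CorrelationResult:
    """Tie-corrected Spearman correlation: Pearson correlation of midranks.

    The p-value uses the t-approximation with n-2 degrees of freedom for
    n >= 10; below that an exact permutation test over all orderings (seeded
    Monte Carlo when n! is infeasible, i.e. n = 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_rho(rx, ry)

    if n >= 10:
        denom = 1.0 - rho * rho
        if denom <= 0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n, method="t-approximation")

    obs = abs(rho) - 1e-12
    if n <= _EXACT_PERM_MAX_N:
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= obs:
                hits += 1
        p = hits / total
    else:
        rng = np.random.default_rng(rng_seed)
        hits = 0
        for _ in range(_MC_PERMUTATIONS):
            if abs(_rank_rho(rx, rng.permutation(ry))) >= obs:
                hits += 1
        p = (hits + 1) / (_MC_PERMUTATIONS + 1)
    return CorrelationResult(rho=rho, p_value=p, n=n, method="permutation")


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of one score against one outcome, low score = positive.

    ``operating_points`` holds (criterion c, sensitivity, specificity) for the
    rule "positive iff score <= c", one row per distinct observed score.
    """

    operating_points: tuple
    auc: float
    auc_se: float
    ci95: tuple
    n_pos: int
    n_neg: int
    positive_meaning: str = ""


def _check_labels(scores: np.ndarray, labels: OutcomeLabels) -> None:
    if len(scores) != len(labels.labels):
        raise ValueError("scores and labels must be aligned")
    if labels.n_pos < 1 or labels.n_neg < 1:
        raise DegenerateLabelsError(
            f"need both outcome classes, got n_pos={labels.n_pos}, n_neg={labels.n_neg}"
        )


def _delong_components(scores: np.ndarray, labels: OutcomeLabels):
    """AUC and DeLong structural components under the low-score-positive rule.

    V10[i] for positive i is the mean over negatives of psi(pos_i, neg_j),
    psi = 1 if pos < neg, 0.5 on ties, 0 otherwise; V01 symmetrically.
    """
    pos = scores[labels.labels == 1].astype(float)
    neg = scores[labels.labels == 0].astype(float)
    ns = np.sort(neg)
    # per positive: fraction of negatives strictly above, plus half the ties
    gt = len(neg) - np.searchsorted(ns, pos, side="right")
    eq = np.searchsorted(ns, pos, side="right") - np.searchsorted(ns, pos, side="left")
    v10 = (gt + 0.5 * eq) / len(neg)
    ps = np.sort(pos)
    lt = np.searchsorted(ps, neg, side="left")
    eqn = np.searchsorted(ps, neg, side="right") - lt
    v01 = (lt + 0.5 * eqn) / len(pos)
    auc = float(v10.mean())
    return auc, v10, v01


def roc(scores, labels: OutcomeLabels) -> RocResult:
    """Empirical ROC with Mann-Whitney AUC and DeLong standard error.

    The AUC equals the trapezoidal area under the operating points by the
    standard Mann-Whitney identity (ties handled with midranks).
    """
    scores = np.asarray(scores, dtype=float)
    _check_labels(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = labels.n_pos, labels.n_neg
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = math.sqrt(max(var, 0.0))
    z = float(sps.norm.ppf(0.975))
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    pos = scores[labels.labels == 1]
    neg = scores[labels.labels == 0]
    pts = []
    for c in np.unique(scores):
        sens = float(np.mean(pos <= c))
        spec = float(np.mean(neg > c))
        pts.append((float(c), sens, spec))
    return RocResult(
        operating_points=tuple(pts),
        auc=auc,
        auc_se=se,
        ci95=ci,
        n_pos=m,
        n_neg=n,
        positive_meaning=labels.positive_meaning,
    )


def trapezoid_auc(roc_result: RocResult) -> float:
    """Trapezoidal area under the empirical ROC polygon (for cross-checking)."""
    # points in (FPR, TPR) = (1 - spec, sens), anchored at (0,0) and (1,1)
    pts = sorted((1.0 - spec, sens) for _, sens, spec in roc_result.operating_points)
    xs = [0.0] + [p[0] for p in pts] + [1.0]
    ys = [0.0] + [p[1] for p in pts] + [1.0]
    return float(np.trapezoid(ys, xs))


@dataclass(frozen=True)
class PairedAucComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float


def delong_paired(scores_a, scores_b, labels: OutcomeLabels) -> PairedAucComparison:
    """DeLong paired test for two correlated AUCs measured on the same patients.

    The variance of the AUC difference comes from the paired covariance of
    the structural components; identical score vectors short-circuit to
    z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scores_a and scores_b must be aligned")
    _check_labels(a, labels)
    auc_a, va10, va01 = _delong_components(a, labels)
    auc_b, vb10, vb01 = _delong_components(b, labels)
    delta = auc_a - auc_b
    if np.array_equal(a, b):
        return PairedAucComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
    m, n = labels.n_pos, labels.n_neg
    d10 = va10 - vb10
    d01 = va01 - vb01
    var = 0.0
    if m > 1:
        var += float(np.var(d10, ddof=1)) / m
    if n > 1:
        var += float(np.var(d01, ddof=1)) / n
    if var <= 0.0:
        raise ZeroVarianceError(
            "paired AUC contrast has zero estimated variance for non-identical scores"
        )
    z = delta / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return PairedAucComparison(auc_a, auc_b, delta, z, min(p, 1.0))


@dataclass(frozen=True)
class YoudenResult:
    j: float
    criterion: float  # positive iff score <= criterion
    sensitivity: float
    specificity: float


def youden(roc_result: RocResult) -> YoudenResult:
    """Maximize J = sensitivity + specificity - 1 over the operating points.

    Ties are broken toward the smallest criterion, i.e. the more specific
    cutoff.
    """
    best = None
    for c, sens, spec in roc_result.operating_points:
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    return YoudenResult(j=j, criterion=c, sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple
    band: str
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_band(value: float) -> str:
    """Reliability interpretation band for an ICC value.

    Cut-points: poor < 0.20, fair 0.21-0.40, moderate 0.41-0.60,
    good 0.61-0.80, very good 0.81-1.0.
    """
    if value <= 0.20:
        return "poor"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "very good"


def icc(ratings) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an n_subjects x k_raters matrix with no missing cells.
    The estimate comes from the two-way ANOVA mean squares
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) and the 95% CI from
    the F-distribution interval of McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix (subjects x raters)")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed; use complete cases")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_total == 0.0 or abs(denom) < 1e-300:
        raise ValueError("degenerate ratings: no variance to partition")
    value = (msr - mse) / denom

    if mse == 0.0 and msc == mse:
        # perfect agreement: the F interval degenerates
        ci = (1.0, 1.0) if value == 1.0 else (value, value)
    else:
        alpha = 0.05
        a = k * value / (n * (1.0 - value)) if value < 1.0 else np.inf
        bb = 1.0 + k * value * (n - 1) / (n * (1.0 - value)) if value < 1.0 else np.inf
        if not np.isfinite(a):
            ci = (value, 1.0)
        else:
            num = (a * msc + bb * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den
            f_l = float(sps.f.ppf(1 - alpha / 2, n - 1, v))
            f_u = float(sps.f.ppf(1 - alpha / 2, v, n - 1))
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            ci = (float(lower), float(upper))
    return IccResult(
        icc=float(value), ci95=ci, band=icc_band(float(value)),
        ms_rows=msr, ms_cols=msc, ms_error=mse,
    )


# ---------------------------------------------------------------------------
# two-group and categorical tests


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum test on midranks; returns (rank-sum of x, p).

    Exact enumeration over all C(N, n_x) group assignments when N <= 12 and
    there are no ties; otherwise a normal approximation with tie correction
    and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    nx, ny = len(x), len(y)
    big_n = nx + ny
    w = float(ranks[:nx].sum())
    mu = nx * (big_n + 1) / 2.0

    has_ties = np.unique(combined).size < big_n
    if big_n <= 12 and not has_ties:
        obs = abs(w - mu) - 1e-12
        hits = total = 0
        for idx in itertools.combinations(range(big_n), nx):
            total += 1
            if abs(float(ranks[list(idx)].sum()) - mu) >= obs:
                hits += 1
        return w, hits / total

    ties = np.array([c for c in pd.Series(combined).value_counts() if c > 1])
    tie_term = float((ties**3 - ties).sum()) if len(ties) else 0.0
    var = nx * ny / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, min(2.0 * float(sps.norm.sf(z)), 1.0)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds ratio, p).  The p-value sums hypergeometric probabilities
    of all tables with the observed margins whose probability does not exceed
    the observed one; the odds ratio is the sample cross-ratio ad/bc with the
    usual inf/0 conventions for zero cells.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins must be positive")

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    n = a + b + c + d
    hg = sps.hypergeom(n, a + b, a + c)
    p_obs = hg.pmf(a)
    kmin = max(0, (a + b) + (a + c) - n)
    kmax = min(a + b, a + c)
    ks = np.arange(kmin, kmax + 1)
    pmfs = hg.pmf(ks)
    p = float(pmfs[pmfs <= p_obs * (1.0 + 1e-7)].sum())
    return odds, min(p, 1.0)


# ---------------------------------------------------------------------------
# cohort-level helpers


def stratified_spearman(
    cohort: pd.DataFrame, score_col: str, outcome_col: str, group_col: str
) -> list[dict]:
    """Per-stratum Spearman correlations (complete cases within stratum).

    Strata with fewer than 3 complete cases are reported as skipped, not
    errored.  Returns one record per stratum:
    {"group", "n", "result" (CorrelationResult or None), "skipped_reason"}.
    """
    for col in (score_col, outcome_col, group_col):
        if col not in cohort.columns:
            raise KeyError(f"unknown column {col!r}")
    out = []
    for group, sub in cohort.groupby(group_col, sort=True, dropna=True):
        sub = sub[[score_col, outcome_col]].dropna()
        rec = {"group": group, "n": len(sub), "result": None, "skipped_reason": None}
        if len(sub) < 3:
            rec["skipped_reason"] = f"fewer than 3 complete cases (n={len(sub)})"
        else:
            try:
                rec["result"] = spearman(sub[score_col], sub[outcome_col])
            except ConstantInputError as exc:
                rec["skipped_reason"] = str(exc)
        out.append(rec)
    return out


def score_outcome_table(scores, labels: OutcomeLabels) -> pd.DataFrame:
    """Counts of patients by observed score value and outcome class.

    Rows are the observed score values (absent levels omitted); columns
    ``n_neg`` / ``n_pos``; marginals reproduce n_neg and n_pos.
    """
    scores = np.asarray(scores)
    lab = labels.labels
    if len(scores) != len(lab):
        raise ValueError("scores and labels must be aligned")
    rows = {}
    for value in np.unique(scores):
        mask = scores == value
        rows[value] = (int((lab[mask] == 0).sum()), int((lab[mask] == 1).sum()))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["n_neg", "n_pos"])
    df.index.name = "score"
    return df


def auc_power_posthoc(
    auc_a: float,
    auc_b: float,
    n_pos: int,
    n_neg: int,
    alpha: float = 0.05,
    corr: float = 0.5,
) -> float:
    """Normal-approximation power for a two-sided test of an AUC difference.

    Each AUC's variance uses the Hanley-McNeil formula; ``corr`` supplies the
    correlation between the two AUCs measured on the same patients.  This is
    an exploratory approximation: different variance models and correlation
    assumptions give different power figures.
    """
    for name, v in (("auc_a", auc_a), ("auc_b", auc_b)):
        if not 0.5 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0.5, 1), got {v}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 <= corr < 1.0:
        raise ValueError("corr must be in [0, 1)")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need positive class sizes")

    def hm_var(a: float) -> float:
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        return (
            a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
        ) / (n_pos * n_neg)

    va, vb = hm_var(auc_a), hm_var(auc_b)
    se = math.sqrt(max(va + vb - 2.0 * corr * math.sqrt(va * vb), 1e-300))
    delta = abs(auc_a - auc_b)
    z_a = float(sps.norm.ppf(1.0 - alpha / 2.0))
    shift = delta / se
    return float(sps.norm.cdf(-z_a + shift) + sps.norm.cdf(-z_a - shift))
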