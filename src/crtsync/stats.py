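"""Outcome definition and cohort statistics.

Exact 2x2 inference (Fisher's exact test with the point-probability
two-sided rule), Woolf odds-ratio confidence intervals, binary logistic
regression with Wald intervals and separation detection, bootstrap internal
validation, paired AUC comparison by the DeLong method, Cohen's kappa, and
the two-sample location tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: [[a, b], [c, d]] with a = exposed/positive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("counts must be non-negative")
        if self.total == 0:
            raise StatsError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Patient-level (exposure, outcome) vectors reconstructed from counts."""
        exposure = np.repeat([1, 1, 0, 0], [self.a, self.b, self.c, self.d])
        outcome = np.repeat([1, 0, 1, 0], [self.a, self.b, self.c, self.d])
        return exposure, outcome


def esv_response(esv_baseline: float, esv_followup: float, fraction: float = 0.15) -> bool:
    """Echocardiographic response: ESV reduction >= 15 % (boundary inclusive)."""
    if esv_baseline <= 0:
        raise StatsError("baseline ESV must be positive")
    return (esv_baseline - esv_followup) / esv_baseline >= fraction


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by the point-probability rule.

    With margins fixed, sums the hypergeometric probabilities of all tables
    whose point probability does not exceed the observed one.  Computed in
    exact integer arithmetic (common denominator C(N, c1)), so ties are
    handled exactly.  A zero margin returns p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    N = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    num = sum(w for w in weights if w <= observed)
    return num / comb(N, c1)


def odds_ratio_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio with the Woolf log-scale confidence interval."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        raise StatsError(
            "zero cell: cross-product OR undefined; use logistic regression "
            "or a continuity-corrected estimate"
        )
    orr = (a * d) / (b * c)
    z = sps.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (orr * np.exp(-z * se), orr * np.exp(z * se))
    return float(orr), (float(ci[0]), float(ci[1]))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n_iter: int
    separation: bool
    level: float = 0.95

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def conf_int(self) -> np.ndarray:
        """Wald CIs for the odds ratios, rows ordered (lo, hi)."""
        z = sps.norm.ppf(0.5 + self.level / 2)
        return np.exp(
            np.column_stack([self.coef - z * self.se, self.coef + z * self.se])
        )

    def predict(self, design: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(len(design)), np.asarray(design, dtype=float)])
        return 1.0 / (1.0 + np.exp(-X @ self.coef))


_SEPARATION_LOGIT = 15.0


def logistic_fit(
    design, outcome, names: list[str] | None = None, maxiter: int = 100
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression (Newton iterations).

    An intercept is always prepended.  Complete or quasi-separation is
    flagged when any coefficient magnitude exceeds 15 on the logit scale
    (Wald intervals are then unreliable).
    """
    import statsmodels.api as sm

    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    if y.size <= X.shape[1]:
        raise StatsError("need more observations than covariates")
    if y.min() == y.max():
        raise StatsError("degenerate outcome: all observations identical")
    names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    import warnings as _warnings

    with _warnings.catch_warnings():
        # separation/convergence warnings are expected and handled via flags
        _warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=maxiter, tol=1e-8, disp=0)
        except Exception:
            # Newton fails under (near-)separation; quasi-Newton still yields a fit
            res = sm.Logit(y, Xc).fit(method="bfgs", maxiter=maxiter * 5, disp=0)
            separation = True
    if np.any(np.abs(res.params) > _SEPARATION_LOGIT):
        separation = True
    return LogisticFit(
        names=["intercept"] + list(names),
        coef=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iter=int(res.mle_retvals.get("iterations", maxiter)),
        separation=separation,
    )


@dataclass
class BootstrapSummary:
    n_resamples: int
    n_skipped: int
    sign_agreement: dict[str, float]
    percentile_ci: dict[str, tuple[float, float]]  # odds-ratio scale


def bootstrap_fit(
    design, outcome, B: int = 1000, seed: int = 0, names: list[str] | None = None
) -> BootstrapSummary:
    """Nonparametric bootstrap of the logistic fit (patients resampled with
    replacement); reports per-covariate sign agreement with the full-data
    fit and percentile CIs on the odds-ratio scale."""
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    full = logistic_fit(X, y, names=names)
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        Xb = X[idx]
        if yb.min() == yb.max() or np.any(Xb.min(axis=0) == Xb.max(axis=0)):
            skipped += 1
            continue
        try:
            draws.append(logistic_fit(Xb, yb, names=names).coef)
        except StatsError:
            skipped += 1
    if not draws:
        raise StatsError("all bootstrap resamples degenerate")
    coefs = np.array(draws)
    sign = {}
    ci = {}
    for j, name in enumerate(full.names):
        ref = np.sign(full.coef[j]) or 1.0
        sign[name] = float(np.mean(np.sign(coefs[:, j]) == ref))
        lo, hi = np.percentile(coefs[:, j], [2.5, 97.5])
        ci[name] = (float(np.exp(lo)), float(np.exp(hi)))
    return BootstrapSummary(
        n_resamples=len(draws), n_skipped=skipped, sign_agreement=sign, percentile_ci=ci
    )


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_and_structural(scores: np.ndarray, outcome: np.ndarray):
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - rp) / n  # per-positive structural components
    v01 = 1.0 - (all_r[m:] - rn) / m
    return auc, v10, v01


def roc_auc_delong(
    scores_base, scores_augmented, outcome
) -> tuple[float, float, float]:
    """Paired comparison of two AUCs on the same patients (DeLong method).

    Returns (AUC_base, AUC_augmented, two-sided p).  Constant score vectors
    give AUC 0.5 and p = 1.
    """
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise StatsError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise StatsError("need both outcome classes for an ROC curve")
    s1 = np.asarray(scores_base, dtype=float)
    s2 = np.asarray(scores_augmented, dtype=float)
    if s1.shape != y.shape or s2.shape != y.shape:
        raise StatsError("score vectors must align with the outcome")
    aucs = []
    V10, V01 = [], []
    for s in (s1, s2):
        if s.min() == s.max():
            m, n = (y == 1).sum(), (y == 0).sum()
            aucs.append(0.5)
            V10.append(np.full(m, 0.5))
            V01.append(np.full(n, 0.5))
        else:
            auc, v10, v01 = _auc_and_structural(s, y)
            aucs.append(auc)
            V10.append(v10)
            V01.append(v01)
    V10 = np.array(V10)
    V01 = np.array(V01)
    m, n = V10.shape[1], V01.shape[1]
    S10 = np.cov(V10)
    S01 = np.cov(V01)
    S = S10 / m + S01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = aucs[1] - aucs[0]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(p)


# ---------------------------------------------------------------------------
# agreement and location tests
# ---------------------------------------------------------------------------

def cohens_kappa(labels_1, labels_2) -> float:
    """Chance-corrected agreement between two raters."""
    l1 = np.asarray(labels_1)
    l2 = np.asarray(labels_2)
    if l1.shape != l2.shape:
        raise StatsError("label vectors must have equal length")
    if len(set(l1) | set(l2)) < 2:
        raise StatsError("kappa undefined with a single category in both raters")
    return float(cohen_kappa_score(l1, l2))


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, welch: bool = False
) -> float:
    """Two-sided two-sample t-test p from summary statistics.

    Pooled-variance Student form (df = n1 + n2 - 2) by default; Welch
    optional.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise StatsError("zero-variance group")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
    return float(res.pvalue)


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p: exact for combined n <= 20 without ties,
    otherwise normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if combined.min() == combined.max():
        return 1.0
    has_ties = len(np.unique(combined)) < combined.size
    if combined.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue)
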