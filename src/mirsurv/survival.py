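"""Two-group survival machinery built from first principles.

This module implements the statistical core of the pipeline: median
stratification of a cohort by a feature's expression, the all-high/all-low
combination split, the Kaplan-Meier product-limit estimator, the two-sample
log-rank test, and a Newton-Raphson Cox proportional-hazards fit for a single
binary group indicator with the Efron correction for tied event times.

Conventions (recorded because the upstream literature leaves them open):

* The median is the midpoint-of-order-statistics (numpy/type-7) median.
* Ties at the median go to the *low* group: a sample is "high" iff its value
  is strictly greater than the median.  This guarantees n_low >= n_high and
  makes the split deterministic.
* In a combination split, a patient is "high" only if high for *every*
  feature in the set, "low" only if low for every feature; everyone else is
  "mixed" and excluded from the two-group comparison.
* The hazard ratio reports high over low: HR > 1 means the high-expression
  group dies faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

HIGH, LOW, MIXED = "high", "low", "mixed"

#: |beta| at which a monotone partial likelihood is declared divergent.
BETA_CAP = 15.0


class DegenerateStratificationError(ValueError):
    """Median split produced an empty group (e.g. a constant feature)."""


class SurvivalInputError(ValueError):
    """Inputs cannot support the requested comparison."""


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

@dataclass
class Stratification:
    """Per-sample high/low/mixed labels from one or more median splits."""

    labels: pd.Series                    # index: sample ids, values in {high,low,mixed}
    thresholds: dict[str, float]         # feature id -> median cutoff

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {HIGH, LOW, MIXED}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH).sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW).sum())

    @property
    def degenerate(self) -> bool:
        return self.n_high == 0 or self.n_low == 0

    def comparison_mask(self) -> pd.Series:
        """Samples entering the two-group comparison (mixed excluded)."""
        return self.labels != MIXED

    def high_indicator(self) -> pd.Series:
        """Boolean high/low indicator over the comparison samples."""
        kept = self.labels[self.comparison_mask()]
        return kept == HIGH


def median_stratify(values: pd.Series, feature_id: str = "feature") -> Stratification:
    """Split samples at the feature's median; high iff strictly above it."""
    v = pd.Series(values, dtype=float)
    if len(v) < 4:
        raise SurvivalInputError("median_stratify needs at least 4 samples")
    if not np.isfinite(v.to_numpy()).all():
        raise SurvivalInputError("median_stratify: non-finite values")
    med = float(np.median(v.to_numpy()))
    labels = pd.Series(np.where(v.to_numpy() > med, HIGH, LOW), index=v.index)
    strat = Stratification(labels=labels, thresholds={feature_id: med})
    if strat.degenerate:
        raise DegenerateStratificationError(
            f"degenerate stratification for {feature_id!r}: one group is empty "
            f"(median {med}, n_high={strat.n_high}, n_low={strat.n_low})")
    return strat


def combo_stratify(strats: dict[str, Stratification]) -> Stratification:
    """Combine per-feature splits into an all-high / all-low / mixed split.

    A singleton combination reduces exactly to its single stratification.
    An empty all-high or all-low group is *not* an error here; callers check
    ``degenerate`` and decide.
    """
    if not strats:
        raise ValueError("combo_stratify needs at least one stratification")
    items = list(strats.values())
    index = items[0].labels.index
    for s in items[1:]:
        if not s.labels.index.equals(index):
            raise ValueError("combo_stratify: stratifications cover different samples")
    mat = np.stack([s.labels.to_numpy() for s in items])
    all_high = (mat == HIGH).all(axis=0)
    all_low = (mat == LOW).all(axis=0)
    labels = np.full(len(index), MIXED, dtype=object)
    labels[all_high] = HIGH
    labels[all_low] = LOW
    thresholds: dict[str, float] = {}
    for s in items:
        thresholds.update(s.thresholds)
    return Stratification(labels=pd.Series(labels, index=index),
                          thresholds=thresholds)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: step function over the distinct event times."""

    times: np.ndarray          # distinct event times, sorted
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n at risk just before each event time
    n_events: np.ndarray       # events at each time
    censor_times: np.ndarray   # times of censored observations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "n_events": self.n_events})


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects shrink the risk set silently."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise SurvivalInputError("km_curve: empty input")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv, risks, deaths = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
        deaths.append(d)
    return KMCurve(times=event_times, survival=np.array(surv),
                   at_risk=np.array(risks, dtype=int),
                   n_events=np.array(deaths, dtype=int),
                   censor_times=np.sort(t[e == 0]))


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test.

    ``groups`` is a boolean array (True = high group).  Returns the 1-df
    chi-square statistic from the observed-minus-expected event sums over
    distinct event times with hypergeometric variance, and its upper-tail
    chi-square(1) p-value.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    if g.sum() == 0 or (~g).sum() == 0:
        raise SurvivalInputError("logrank_test: one group is empty")
    if e.sum() == 0:
        raise SurvivalInputError("logrank_test: no events — no information")

    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        dying = (t == et) & (e == 1)
        d = int(dying.sum())
        d1 = int((dying & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate, Efron ties
# ---------------------------------------------------------------------------

@dataclass
class SurvivalStats:
    """One two-group comparison: Cox log-HR plus the log-rank test."""

    beta: float
    hr: float
    se_beta: float
    logrank_chi2: float
    logrank_p: float
    n_high: int
    n_low: int
    n_events: int
    diverged: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "hr": self.hr, "se_beta": self.se_beta,
            "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
            "n_high": self.n_high, "n_low": self.n_low,
            "n_events": self.n_events, "diverged": self.diverged,
        }


def _efron_terms(times, events, groups):
    """Flattened Efron denominator coefficients.

    For each distinct event time j with d_j events of which s_j are in the
    high group, and risk-set counts (r1_j high, r0_j low), the Efron partial
    log-likelihood is

        l(b) = sum_j s_j*b - sum_j sum_{l=0}^{d_j-1} log(A_jl e^b + B_jl)

    with A_jl = r1_j - (l/d_j) s_j and B_jl = r0_j - (l/d_j)(d_j - s_j).
    Returns (sum_j s_j, A, B) with A, B flattened over (j, l).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    event_times = np.unique(t[e == 1])
    A_parts, B_parts, s_total = [], [], 0
    for et in event_times:
        at_risk = t >= et
        r1 = int((at_risk & g).sum())
        r0 = int((at_risk & ~g).sum())
        dying = (t == et) & (e == 1)
        d = int(dying.sum())
        s = int((dying & g).sum())
        s_total += s
        frac = np.arange(d) / d
        A_parts.append(r1 - frac * s)
        B_parts.append(r0 - frac * (d - s))
    return s_total, np.concatenate(A_parts), np.concatenate(B_parts)


def efron_loglik(beta, s_total, A, B):
    """Efron partial log-likelihood; vectorized over a beta array."""
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    phi = A[None, :] * np.exp(b)[:, None] + B[None, :]
    ll = s_total * b - np.log(phi).sum(axis=1)
    return ll if np.ndim(beta) else float(ll[0])


def cox_binary_fit(times, events, groups, *, max_iter: int = 100,
                   tol: float = 1e-8) -> SurvivalStats:
    """Cox proportional-hazards fit for a binary group indicator.

    Maximizes the Efron-corrected partial likelihood by Newton-Raphson
    (stopping at |delta beta| < 1e-8); the hazard ratio is exp(beta) with the
    high group in the numerator.  A monotone likelihood (all information
    pointing one way) is reported with |beta| capped at 15 and the
    ``diverged`` flag set rather than raised.  The log-rank fields are filled
    by :func:`logrank_test` on the same data.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    n_high, n_low = int(g.sum()), int((~g).sum())
    if n_high == 0 or n_low == 0:
        raise SurvivalInputError("cox_binary_fit: one group is empty")
    n_events = int(e.sum())
    if n_events == 0:
        raise SurvivalInputError("cox_binary_fit: no events")

    s_total, A, B = _efron_terms(t, e, g)

    def derivatives(b):
        eb = np.exp(b)
        u = A * eb / (A * eb + B)
        grad = s_total - u.sum()
        hess = -(u * (1.0 - u)).sum()
        return grad, hess

    beta = 0.0
    diverged = False
    converged = False
    ll = efron_loglik(beta, s_total, A, B)
    for _ in range(max_iter):
        grad, hess = derivatives(beta)
        if hess >= -1e-12:          # flat likelihood: no usable curvature
            diverged = abs(grad) > 1e-8
            converged = not diverged
            break
        step = -grad / hess
        # dampen huge steps; keeps monotone likelihoods from overflowing
        step = float(np.clip(step, -5.0, 5.0))
        new_beta = beta + step
        new_ll = efron_loglik(new_beta, s_total, A, B)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = efron_loglik(new_beta, s_total, A, B)
            halvings += 1
        beta, ll = new_beta, new_ll
        if abs(beta) >= BETA_CAP:
            beta = float(np.sign(beta) * BETA_CAP)
            diverged = True
            break
        if abs(step) < tol:
            converged = True
            break

    if not converged and not diverged:
        diverged = True
        beta = float(np.clip(beta, -BETA_CAP, BETA_CAP))

    _, hess = derivatives(beta)
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else float("inf")
    chi2, p = logrank_test(t, e, g)
    return SurvivalStats(
        beta=float(beta), hr=float(np.exp(beta)), se_beta=se,
        logrank_chi2=chi2, logrank_p=p,
        n_high=n_high, n_low=n_low, n_events=n_events,
        diverged=diverged,
        note="monotone likelihood, |beta| capped" if diverged else "",
    )


def two_group_stats(clinical: pd.DataFrame, strat: Stratification) -> SurvivalStats:
    """Cox + log-rank for one stratification; mixed samples are excluded."""
    mask = strat.comparison_mask()
    kept = clinical.loc[strat.labels.index[mask]]
    groups = strat.high_indicator().to_numpy()
    return cox_binary_fit(kept["time"].to_numpy(), kept["event"].to_numpy(), groups)
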