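"""Survival and exact-test statistics.

Kaplan-Meier estimation, the two-group logrank test (two- and one-sided),
univariate hazard ratios, multivariate Cox proportional-hazards fits with
Breslow tie handling, and Fisher's exact test for 2x2 tables.

The logrank and Cox routines are implemented here because the pipeline needs
per-group observed/expected event counts (for the prespecified one-sided
direction rule) and Breslow tie handling with Wald intervals; both are
cross-checked against independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .errors import DataError, SingularMatrixError, UndefinedTestError

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogrankResult",
    "CoxFit",
    "FisherResult",
    "km_estimate",
    "logrank_test",
    "univariate_hr",
    "cox_ph",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: time in months (> 0) and event flag {0, 1}."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1 or len(time) != len(event):
            raise DataError("time and event must be equal-length 1-D vectors")
        if len(time) == 0:
            raise DataError("empty survival data")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise DataError("times must be finite and strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise DataError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        mask = np.asarray(mask)
        return SurvivalData(self.time[mask], self.event[mask])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, time_col: str = "os_months", event_col: str = "os_event"
    ) -> "SurvivalData":
        return cls(df[time_col].to_numpy(float), df[event_col].to_numpy())


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(s: SurvivalData) -> KMCurve:
    """Kaplan-Meier curve of one stratum.

    Censored observations leave the risk set without contributing a factor;
    with no events the estimate is identically 1 (empty curve).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(s.time, s.event)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(int),
        events=ev["observed"].to_numpy(int),
    )


# ---------------------------------------------------------------------------
# logrank test


def _logrank_terms(time: np.ndarray, event: np.ndarray, in_a: np.ndarray):
    """Observed/expected events for group A and hypergeometric variance.

    Inputs need not be sorted. Returns (O_a, E_a, V, D) where D is the total
    event count.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    g = in_a[order].astype(float)

    # block boundaries of tied times
    first = np.concatenate(([True], t[1:] != t[:-1]))
    idx = np.flatnonzero(first)
    n = len(t)

    cg = np.cumsum(g)
    before = np.where(idx > 0, cg[idx - 1], 0.0)
    n1 = g.sum() - before            # group-A members at risk at each distinct time
    nj = n - idx                     # total at risk
    d = np.add.reduceat(e.astype(float), idx)
    d1 = np.add.reduceat(e * g, idx)

    has_event = d > 0
    nj = nj[has_event].astype(float)
    n1 = n1[has_event]
    d = d[has_event]
    d1 = d1[has_event]

    frac = n1 / nj
    expected = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * frac * (1.0 - frac) * (nj - d) / np.maximum(nj - 1.0, 1.0)
    var[nj <= 1] = 0.0
    return float(d1.sum()), float(expected.sum()), float(var.sum()), float(d.sum())


def logrank_pvalue(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> float:
    """Two-sided logrank p-value on raw arrays (hot path used by the CV loop)."""
    o_a, e_a, v, _ = _logrank_terms(time, event, in_a)
    if v <= 0.0:
        return 1.0
    stat = (o_a - e_a) ** 2 / v
    return float(sps.chi2.sf(stat, 1))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_two_sided: float
    p_one_sided: float | None
    observed: tuple[float, float]     # events in (a, b)
    expected: tuple[float, float]
    variance: float

    @property
    def p(self) -> float:
        return self.p_two_sided


def logrank_test(
    a: SurvivalData, b: SurvivalData, adverse_group: str | None = None
) -> LogrankResult:
    """Two-group logrank test with hypergeometric variance at tied event times.

    Parameters
    ----------
    adverse_group : "a", "b" or None
        Prespecified direction for a one-sided test: the group expected to
        have the higher hazard. The one-sided p is half the two-sided p when
        the observed excess of events falls in the adverse group, and
        ``1 - p_two/2`` otherwise.
    """
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    if adverse_group not in (None, "a", "b"):
        raise DataError("adverse_group must be 'a', 'b' or None")
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    in_a = np.concatenate([np.ones(len(a), bool), np.zeros(len(b), bool)])
    d_total = event.sum()
    if d_total == 0:
        raise UndefinedTestError("logrank undefined: no events in either group")

    o_a, e_a, v, d = _logrank_terms(time, event, in_a)
    o_b = d - o_a
    e_b = d - e_a
    stat = 0.0 if v <= 0 else (o_a - e_a) ** 2 / v
    p_two = float(np.clip(sps.chi2.sf(stat, 1), 0.0, 1.0))

    p_one = None
    if adverse_group is not None:
        o_adv, e_adv = (o_a, e_a) if adverse_group == "a" else (o_b, e_b)
        p_one = p_two / 2.0 if o_adv >= e_adv else 1.0 - p_two / 2.0
    return LogrankResult(
        statistic=float(stat),
        p_two_sided=p_two,
        p_one_sided=p_one,
        observed=(o_a, o_b),
        expected=(e_a, e_b),
        variance=v,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


@dataclass(frozen=True)
class CoxFit:
    """Partial-likelihood fit: per covariate HR = exp(coef) with Wald CI/p."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    estimable: bool = True
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
                "se": self.se,
            },
            index=list(self.names),
        )

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]),
            "HR": float(self.hr[i]),
            "ci_lower": float(self.ci_lower[i]),
            "ci_upper": float(self.ci_upper[i]),
            "p": float(self.p[i]),
        }


def _breslow_blocks(time: np.ndarray, event: np.ndarray, X: np.ndarray):
    """Sort descending by time and return per-distinct-event-time data.

    With a descending sort the risk set of time t is the prefix of rows with
    time >= t, so risk-set sums are cumulative sums up to the block end.
    """
    order = np.argsort(-time, kind="mergesort")
    t, e, Xs = time[order], event[order], X[order]
    first = np.concatenate(([True], t[1:] != t[:-1]))
    starts = np.flatnonzero(first)
    ends = np.concatenate([starts[1:], [len(t)]]) - 1  # inclusive block ends
    d = np.add.reduceat(e.astype(float), starts)
    # sum of covariates over events in each block
    xe = Xs * e[:, None]
    s = np.add.reduceat(xe, starts, axis=0)
    keep = d > 0
    return t, e, Xs, ends[keep], d[keep], s[keep]


def _cox_loglik_grad_hess(beta, Xs, ends, d, s):
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    W = cw[ends]
    WX = cwx[ends]
    WXX = cwxx[ends]
    mu = WX / W[:, None]

    ll = float((s * beta).sum() - (d * np.log(W)).sum())
    grad = s.sum(axis=0) - (d[:, None] * mu).sum(axis=0)
    hess = -np.einsum("j,jkl->kl", d, WXX / W[:, None, None] - mu[:, :, None] * mu[:, None, :])
    return ll, grad, hess


def cox_ph(
    covariates: pd.DataFrame | np.ndarray,
    s: SurvivalData,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Breslow tie handling).

    Newton-Raphson with step halving on the Breslow partial likelihood;
    Wald 95% confidence intervals and p-values from the inverse observed
    information. Collinear or constant covariate columns raise
    :class:`SingularMatrixError` naming the offenders; monotone likelihood
    (complete separation) is reported as a non-estimable fit.
    """
    if isinstance(covariates, pd.DataFrame):
        names = tuple(str(c) for c in covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if np.isnan(X).any():
        raise DataError("covariates contain missing values; no imputation is done")
    n, p = X.shape
    if n != len(s):
        raise DataError("covariates and survival data have different lengths")
    if n <= p:
        raise DataError(f"need more samples ({n}) than covariates ({p})")
    if s.n_events == 0:
        raise UndefinedTestError("no events: partial likelihood is constant")

    # collinearity screen (constant columns and rank deficiency)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    bad = [names[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise SingularMatrixError(f"constant covariate column(s): {', '.join(bad)}")
    if np.linalg.matrix_rank(Xc) < p:
        # name a minimal offender via QR pivoting on the correlation structure
        _, r = np.linalg.qr(Xc / sd)
        dep = [names[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(r[0, 0]))]
        raise SingularMatrixError(
            f"collinear covariates (rank {np.linalg.matrix_rank(Xc)} < {p}): "
            f"{', '.join(dep) or 'unidentified'}"
        )

    _, _, Xs, ends, d, ssum = _breslow_blocks(s.time, s.event, X)

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, Xs, ends, d, ssum)
    message = ""
    estimable = True
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            estimable = False
            message = "singular information matrix during Newton iteration"
            break
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, Xs, ends, d, ssum)
        halves = 0
        while new_ll < ll - 1e-12 and halves < 30:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, Xs, ends, d, ssum)
            halves += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 25:
            estimable = False
            message = "diverging coefficient: likely complete separation (monotone likelihood)"
            break
        if np.max(np.abs(grad)) < tol * (1 + abs(ll)):
            break
    else:
        if np.max(np.abs(grad)) > 1e-4:
            estimable = False
            message = "Newton-Raphson failed to converge"

    if estimable and np.max(np.abs(beta)) > 15:
        # a |log HR| this large only arises under monotone likelihood
        estimable = False
        message = "diverging coefficient: likely complete separation (monotone likelihood)"

    info = -hess
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        estimable = False
        message = message or "non-positive-definite information matrix"
        se = np.full(p, np.nan)

    z = sps.norm.ppf(0.975)
    with np.errstate(invalid="ignore", over="ignore"):
        wald = beta / se
        pvals = 2.0 * sps.norm.sf(np.abs(wald))
        ci_lower = np.exp(beta - z * se)
        ci_upper = np.exp(beta + z * se)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        p=pvals,
        log_likelihood=ll,
        n=n,
        n_events=s.n_events,
        estimable=estimable,
        message=message,
    )


def cox_partial_loglik(
    beta: np.ndarray, covariates: np.ndarray, s: SurvivalData
) -> float:
    """Breslow log partial likelihood at an arbitrary coefficient vector."""
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    _, _, Xs, ends, d, ssum = _breslow_blocks(s.time, s.event, X)
    ll, _, _ = _cox_loglik_grad_hess(np.asarray(beta, float), Xs, ends, d, ssum)
    return ll


def univariate_hr(a: SurvivalData, b: SurvivalData) -> CoxFit:
    """Cox fit of a single binary indicator: HR = hazard(b) / hazard(a).

    Complete separation (e.g. one group entirely event-free so the fit
    diverges) is reported as a non-estimable :class:`CoxFit`, not an error.
    """
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    time = np.concatenate([a.time, b.time])
    event = np.concatenate([a.event, b.event])
    group = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    s = SurvivalData(time, event)
    return cox_ph(pd.DataFrame({"group": group}), s)


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    odds_ratio: float


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test for a 2x2 contingency table.

    Two-sidedness follows the "sum of small p" convention: the p-value sums
    the probabilities of all tables in the hypergeometric support that are no
    more probable than the observed one (with a 1e-7 relative tolerance).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataError("expected a 2x2 table")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise DataError("counts must be non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise DataError("table total must be positive")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return FisherResult(
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        p_two_sided=float(min(p, 1.0)),
        odds_ratio=float(odds),
    )
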