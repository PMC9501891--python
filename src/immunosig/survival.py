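"""Right-censored survival analysis: Kaplan–Meier, log-rank, two-group Cox.

Everything here is implemented from first principles on (time, event)
arrays: the product-limit estimator with events preceding censorings at
tied times, the Mantel–Haenszel log-rank test summing hypergeometric
observed-minus-expected events over distinct event times, and a
single-binary-covariate Cox proportional-hazards model maximized by Newton
iterations with Efron handling of tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConvergenceError, SurvivalTestError

__all__ = [
    "KMCurve",
    "SurvivalComparison",
    "km_estimate",
    "logrank_test",
    "cox_two_group_hr",
    "compare_survival",
]


def _check_times(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and nonnegative")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValueError("events must be 0 or 1")
    return t, e


@dataclass
class KMCurve:
    """Product-limit survival estimate on the distinct event-time grid."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # subjects at risk just before each event time
    n_events: np.ndarray       # events at each event time
    censor_times: np.ndarray   # times of censored subjects
    n_subjects: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t); S(0) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    @property
    def median(self) -> float:
        """First time where S(t) <= 0.5, or NaN when never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("nan")

    def plot(self, ax=None, label=None, **kwargs):
        """Step plot of the curve with censoring ticks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[0.0], self.times])
        ys = np.concatenate([[1.0], self.survival])
        ax.step(xs, ys, where="post", label=label, **kwargs)
        if self.censor_times.size:
            ax.plot(self.censor_times, self.survival_at(self.censor_times),
                    linestyle="none", marker="|", color=ax.lines[-1].get_color())
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    At tied times events are processed before censorings, so subjects
    censored at an event time still count in that time's risk set.
    """
    t, e = _check_times(times, events)
    event_times = np.unique(t[e == 1])
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size, dtype=float)
    s = 1.0
    for i, et in enumerate(event_times):
        at_risk[i] = int((t >= et).sum())   # censored at et remain at risk
        d[i] = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        censor_times=np.sort(t[e == 0]),
        n_subjects=n,
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Mantel–Haenszel log-rank test; returns (chi_square, two-sided p).

    Sums observed minus hypergeometric-expected group-A events over the
    pooled distinct event times; chi-square with 1 df.  Symmetric under
    group swap.
    """
    ta, ea = _check_times(times_a, events_a)
    tb, eb = _check_times(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise SurvivalTestError("log-rank test requires at least one event")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        d_a = int((dead & (grp == 0)).sum())
        exp_a = d * n_a / n_tot
        o_minus_e += d_a - exp_a
        if n_tot > 1:
            var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def _cox_loglik_grad_hess(beta: float, t, e, x):
    """Efron partial log-likelihood with derivatives for a scalar covariate."""
    eta = beta * x
    r = np.exp(eta)
    ll = float((eta[e == 1]).sum())
    grad = float((x[e == 1]).sum())
    hess = 0.0
    for et in np.unique(t[e == 1]):
        risk = t >= et
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        s0 = r[risk].sum()
        s1 = (r[risk] * x[risk]).sum()
        s2 = (r[risk] * x[risk] ** 2).sum()
        d0 = r[dead].sum()
        d1 = (r[dead] * x[dead]).sum()
        d2 = (r[dead] * x[dead] ** 2).sum()
        for l in range(d):
            f = l / d
            a0 = s0 - f * d0
            a1 = s1 - f * d1
            a2 = s2 - f * d2
            ll -= np.log(a0)
            grad -= a1 / a0
            hess -= a2 / a0 - (a1 / a0) ** 2
    return ll, grad, hess


def cox_two_group_hr(times, events, group, tol: float = 1e-8, max_iter: int = 100):
    """Hazard ratio (group 1 vs group 0) from a single-covariate Cox model.

    Newton–Raphson on the Efron partial likelihood; Wald 95% CI on the log
    scale.  Complete separation of events (monotone likelihood) raises
    :class:`ConvergenceError` carrying the direction of divergence.

    Returns ``(hr, (ci_low, ci_high), p)``.
    """
    t, e = _check_times(times, events)
    x = np.asarray(group, dtype=float)
    if not set(np.unique(x)).issubset({0.0, 1.0}):
        raise ValueError("group must be binary 0/1")
    if x.min() == x.max():
        raise ValueError("both groups must be nonempty")
    if e.sum() == 0:
        raise SurvivalTestError("Cox model requires at least one event")
    beta = 0.0
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_grad_hess(beta, t, e, x)
        if hess >= 0 or not np.isfinite(hess):
            raise ConvergenceError("degenerate Cox information", direction=np.sign(grad) or None)
        step = -grad / hess
        # damped update guards overshoot on near-separated data
        step = float(np.clip(step, -2.0, 2.0))
        beta_new = beta + step
        if abs(beta_new) > 20:
            raise ConvergenceError(
                "monotone partial likelihood (complete separation of events)",
                direction=int(np.sign(beta_new)),
            )
        if abs(step) < tol and abs(grad) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        if abs(grad) > 1e-4:
            raise ConvergenceError("Cox Newton iterations did not converge",
                                   direction=int(np.sign(grad)) or None)
    _, _, hess = _cox_loglik_grad_hess(beta, t, e, x)
    se = float(np.sqrt(-1.0 / hess))
    z = sps.norm.ppf(0.975)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    p = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return hr, ci, p


@dataclass
class SurvivalComparison:
    """Two-stratum survival comparison: KM curves, medians, log-rank, HR."""

    labels: tuple[str, str]          # (reference, comparison); HR = comparison vs reference
    curves: dict[str, KMCurve] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    chi_square: float = np.nan
    p: float = np.nan
    hr: float = np.nan
    hr_ci: tuple[float, float] = (np.nan, np.nan)
    hr_p: float = np.nan
    hr_note: str = ""

    def median_text(self, label: str) -> str:
        m = self.medians[label]
        return "not reached" if np.isnan(m) else f"{m:.3g}"


def compare_survival(times, events, strata, reference: str, comparison: str) -> SurvivalComparison:
    """KM curves, medians, log-rank test and Cox HR for two strata.

    The hazard ratio is ``comparison`` vs ``reference`` (e.g. high-score vs
    low-score, or responder vs non-responder).  A non-convergent Cox fit
    (complete separation) is reported in ``hr_note`` rather than as a
    number.
    """
    t, e = _check_times(times, events)
    s = np.asarray(strata, dtype=object)
    masks = {lab: s == lab for lab in (reference, comparison)}
    for lab, m in masks.items():
        if not m.any():
            raise ValueError(f"stratum {lab!r} is empty")
    curves = {lab: km_estimate(t[m], e[m]) for lab, m in masks.items()}
    chi2, p = logrank_test(
        t[masks[reference]], e[masks[reference]],
        t[masks[comparison]], e[masks[comparison]],
    )
    out = SurvivalComparison(
        labels=(reference, comparison),
        curves=curves,
        medians={lab: c.median for lab, c in curves.items()},
        chi_square=chi2,
        p=p,
    )
    x = masks[comparison].astype(float)
    keep = masks[reference] | masks[comparison]
    try:
        hr, ci, hr_p = cox_two_group_hr(t[keep], e[keep], x[keep])
        out.hr, out.hr_ci, out.hr_p = hr, ci, hr_p
    except ConvergenceError as exc:
        direction = "toward zero" if (exc.direction or 0) < 0 else "toward infinity"
        out.hr_note = f"Cox fit did not converge ({direction}): {exc}"
    return out
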