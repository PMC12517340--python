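"""Time-to-onset analysis with a two-parameter Weibull hazard classification.

For each (case, drug, event) the onset interval is the whole-day difference
between the event onset date and the earliest dosing start date on or before
it, plus a 0.5-day offset (so a same-day onset counts as half a day and no
interval is zero).  Records missing a day-level date are excluded, not
imputed, and onsets beyond a 730-day (2-year) cap are dropped.

The surviving onset times are fitted by maximum likelihood to a Weibull
distribution with scale alpha (days) and shape beta,

    f(t) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta),

with no censoring.  The shape parameter indexes the hazard profile:
beta < 1 means a decreasing hazard (early/initial-failure type), beta = 1 a
constant hazard (random), beta > 1 an increasing hazard (wear-out type).
The default classification compares the 95% CI of beta against 1 so that
noise around 1 is not over-read; a point-estimate rule is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dates import ParsedDate, parse_date
from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError

__all__ = [
    "OnsetRecord",
    "WeibullFit",
    "onset_days",
    "apply_cap",
    "fit_weibull",
    "classify_hazard",
    "tto_summary",
    "collect_onsets",
    "CAP_DAYS",
]

#: maximum onset considered, in days (2 years)
CAP_DAYS = 730.0

#: the half-day offset added to every whole-day onset difference
ONSET_OFFSET = 0.5


@dataclass(frozen=True)
class OnsetRecord:
    """Per (case, drug, event) onset interval, or the reason it was excluded."""

    case_id: str
    drug_name: str
    pt_term: str
    onset_days: float | None = None
    excluded_reason: str | None = None  # missing_date | partial_date | no_start_before_onset | beyond_cap

    @property
    def usable(self) -> bool:
        return self.excluded_reason is None and self.onset_days is not None


@dataclass(frozen=True)
class WeibullFit:
    """Weibull MLE with observed-information CIs and the hazard classification."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n_used: int
    loglik: float

    @property
    def hazard_type(self) -> str:
        return classify_hazard(self)


def _as_parsed(value) -> ParsedDate:
    return value if isinstance(value, ParsedDate) else parse_date(value)


def onset_days(start_dates, onset_date, *, case_id: str = "", drug_name: str = "",
               pt_term: str = "") -> OnsetRecord:
    """Onset interval for one record: (onset - earliest qualifying start) + 0.5.

    ``start_dates`` is an iterable of raw date strings or :class:`ParsedDate`;
    the earliest start on or before the onset date is used.  Records with a
    missing or partial onset date, no day-level start date, or every start
    after the onset are excluded with the corresponding reason.
    """
    meta = dict(case_id=case_id, drug_name=drug_name, pt_term=pt_term)
    onset = _as_parsed(onset_date)
    if onset.is_missing:
        return OnsetRecord(**meta, excluded_reason="missing_date")
    if onset.is_partial:
        return OnsetRecord(**meta, excluded_reason="partial_date")

    starts = [_as_parsed(s) for s in start_dates]
    full = [s.date for s in starts if s.is_full]
    if not full:
        if any(s.is_partial for s in starts):
            return OnsetRecord(**meta, excluded_reason="partial_date")
        return OnsetRecord(**meta, excluded_reason="missing_date")
    qualifying = [d for d in full if d <= onset.date]
    if not qualifying:
        return OnsetRecord(**meta, excluded_reason="no_start_before_onset")
    days = (onset.date - min(qualifying)).days + ONSET_OFFSET
    return OnsetRecord(**meta, onset_days=days)


def apply_cap(records, cap_days: float = CAP_DAYS) -> list[OnsetRecord]:
    """Exclude onsets beyond the cap (a day-``cap`` onset, 730.5 after the
    offset, is excluded; 729.5 is retained)."""
    out = []
    for r in records:
        if r.usable and r.onset_days > cap_days:
            out.append(OnsetRecord(case_id=r.case_id, drug_name=r.drug_name,
                                   pt_term=r.pt_term, excluded_reason="beyond_cap"))
        else:
            out.append(r)
    return out


def collect_onsets(db, drug_name: str, pt_term: str, cap_days: float = CAP_DAYS) -> list[OnsetRecord]:
    """Onset records for every case reporting the pair in a ReportDatabase."""
    key = drug_name.strip().casefold()
    starts_by_case: dict[str, list] = {}
    for cid, name, start in zip(db.drugs["case_id"], db.drugs["drug_name"], db.drugs["start_date"]):
        if name.strip().casefold() == key:
            starts_by_case.setdefault(cid, []).append(start)
    ev = db.events[db.events["pt_term"] == pt_term]
    records = [
        onset_days(starts_by_case.get(cid, []), onset,
                   case_id=cid, drug_name=drug_name, pt_term=pt_term)
        for cid, onset in zip(ev["case_id"], ev["onset_date"])
        if cid in starts_by_case
    ]
    return apply_cap(records, cap_days)


def _weibull_loglik(x: np.ndarray, alpha: float, beta: float) -> float:
    n = x.size
    return (n * math.log(beta) - n * beta * math.log(alpha)
            + (beta - 1) * float(np.sum(np.log(x))) - float(np.sum((x / alpha) ** beta)))


def _profile_equation(k: float, x: np.ndarray, mean_log: float) -> float:
    # MLE shape equation: sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0
    xk = np.exp(k * np.log(x))
    return float(np.sum(xk * np.log(x)) / np.sum(xk)) - 1.0 / k - mean_log


def fit_weibull(onset_days_list, *, min_n: int = 10, ci_level: float = 0.95) -> WeibullFit:
    """Two-parameter Weibull MLE on uncensored onset times.

    The shape is found by deterministic bracketed root-finding on the
    profile-likelihood equation (no random initialization); the scale then
    has a closed form.  CIs come from the observed information matrix on the
    (log alpha, log beta) scale, back-transformed, so they respect
    positivity.
    """
    x = np.asarray(list(onset_days_list), dtype=float)
    if x.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} onset times, got {x.size}")
    if np.any(x <= 0):
        raise ConfigurationError("onset times must be positive")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all onset times identical; the Weibull MLE diverges")

    from scipy.optimize import brentq

    mean_log = float(np.mean(np.log(x)))
    lo, hi = 1e-3, 1.0
    while _profile_equation(hi, x, mean_log) < 0 and hi < 1e4:
        hi *= 2.0
    beta = float(brentq(_profile_equation, lo, hi, args=(x, mean_log), xtol=1e-12, rtol=1e-14))
    alpha = float(np.mean(x ** beta) ** (1.0 / beta))
    loglik = _weibull_loglik(x, alpha, beta)

    # observed information on (log alpha, log beta) by central differences
    la, lb = math.log(alpha), math.log(beta)
    h = 1e-5

    def ll(u, v):
        return _weibull_loglik(x, math.exp(u), math.exp(v))

    d2a = (ll(la + h, lb) - 2 * loglik + ll(la - h, lb)) / h**2
    d2b = (ll(la, lb + h) - 2 * loglik + ll(la, lb - h)) / h**2
    dab = (ll(la + h, lb + h) - ll(la + h, lb - h) - ll(la - h, lb + h) + ll(la - h, lb - h)) / (4 * h**2)
    info = -np.array([[d2a, dab], [dab, d2b]])
    cov = np.linalg.inv(info)
    from scipy import stats as _stats

    z = float(_stats.norm.ppf(0.5 + ci_level / 2))
    se_la, se_lb = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
    return WeibullFit(
        alpha=alpha, beta=beta,
        alpha_ci=(math.exp(la - z * se_la), math.exp(la + z * se_la)),
        beta_ci=(math.exp(lb - z * se_lb), math.exp(lb + z * se_lb)),
        n_used=int(x.size), loglik=loglik)


def classify_hazard(fit: WeibullFit, rule: str = "ci") -> str:
    """Hazard-profile label from the fitted shape parameter.

    ``ci`` rule (default): wear_out if the beta CI lies above 1,
    early_failure if it lies below 1, random otherwise.  ``point`` rule
    compares the point estimate directly (beta exactly 1 → random).
    """
    if rule == "ci":
        lo, hi = fit.beta_ci
        if lo > 1.0:
            return "wear_out"
        if hi < 1.0:
            return "early_failure"
        return "random"
    if rule == "point":
        if fit.beta > 1.0:
            return "wear_out"
        if fit.beta < 1.0:
            return "early_failure"
        return "random"
    raise ConfigurationError(f"unknown classify rule {rule!r}")


def tto_summary(onset_days_list) -> dict:
    """Five-number summary with 1.5*IQR whisker bounds (box-plot statistics).

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme observations within 1.5 IQR of the quartiles.
    """
    x = np.sort(np.asarray(list(onset_days_list), dtype=float))
    if x.size == 0:
        raise InsufficientDataError("cannot summarize an empty onset list")
    q1, med, q3 = (float(v) for v in np.quantile(x, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    return {
        "n": int(x.size),
        "min": float(x[0]),
        "q1": q1,
        "median": med,
        "q3": q3,
        "max": float(x[-1]),
        "whisker_low": float(inside[0]),
        "whisker_high": float(inside[-1]),
    }
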