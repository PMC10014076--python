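"""Four-parameter logistic (4PL) dose-response fitting and EC50 comparison.

The model is

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x)**hill)

fitted by least squares with ec50 parameterized internally as log10(ec50).
The unstimulated control (x = 0) stays in the fit: for hill > 0 the curve's
limit at zero dose is ``bottom``, so x = 0 points contribute the residual
against the bottom asymptote.  EC50 differences between two datasets are
tested with the extra-sum-of-squares F test (null model: shared ec50, all
other parameters per-dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .exceptions import DomainError

__all__ = [
    "DoseResponseFit",
    "fit_4pl",
    "ec50_fold_change",
    "compare_ec50_f_test",
    "four_pl",
    "dose_response_points",
]

HILL_BOUNDS = (0.1, 10.0)
HILL_STARTS = (0.5, 1.0, 2.0)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    def predict(self, doses) -> np.ndarray:
        return four_pl(np.asarray(doses, dtype=float),
                       self.bottom, self.top, self.ec50, self.hill)


def four_pl(x, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """Evaluate the 4PL curve; x = 0 maps to the bottom asymptote (hill > 0)."""
    x = np.asarray(x, dtype=float)
    y = np.full(x.shape, float(bottom))
    pos = x > 0
    # 1/(1 + (ec50/x)^hill) = expit(hill * (ln x - ln ec50)), stable for all x
    frac = special.expit(hill * (np.log(x[pos]) - np.log(ec50)))
    y[pos] = bottom + (top - bottom) * frac
    return y


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray):
    bottom, top, lec50, hill = theta
    return w * (four_pl(x, bottom, top, 10.0 ** lec50, hill) - y)


def _lec50_bounds(x: np.ndarray) -> tuple[float, float]:
    pos = x[x > 0]
    return float(np.log10(pos.min() / 100.0)), float(np.log10(x.max() * 100.0))


def _starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    lo, hi = float(y.min()), float(y.max())
    half = (lo + hi) / 2.0
    pos = x > 0
    # dose nearest the half-range crossing
    k = int(np.argmin(np.abs(y[pos] - half)))
    ec50_0 = float(x[pos][k])
    return [np.array([lo, hi, np.log10(ec50_0), h]) for h in HILL_STARTS]


def fit_4pl(doses, responses, weights=None) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start over the hill slope.

    Non-convergence is reported in the ``converged`` flag with diagnostics in
    ``message``; it does not raise.  Requires >= 4 distinct positive doses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("doses and responses must be 1-D and equal length")
    if np.any(x < 0) or not np.all(np.isfinite(y)):
        raise DomainError("doses must be >= 0 and responses finite")
    if len(np.unique(x[x > 0])) < 4:
        raise DomainError("4PL fit needs >= 4 distinct positive doses")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    llo, lhi = _lec50_bounds(x)
    lower = np.array([-np.inf, -np.inf, llo, HILL_BOUNDS[0]])
    upper = np.array([np.inf, np.inf, lhi, HILL_BOUNDS[1]])
    best = None
    msgs = []
    for theta0 in _starts(x, y):
        theta0[2] = np.clip(theta0[2], llo, lhi)
        try:
            res = optimize.least_squares(
                _residuals, theta0, args=(x, y, w), bounds=(lower, upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # keep the flagged-fit contract
            msgs.append(str(exc))
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
        msgs.append(res.message)
    if best is None:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), ec50=float("nan"),
            hill=float("nan"), rss=float("inf"), n_points=len(x),
            converged=False, message="; ".join(msgs),
        )
    rss, res = best
    bottom, top, lec50, hill = res.x
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), ec50=float(10.0 ** lec50),
        hill=float(hill), rss=rss, n_points=len(x),
        converged=bool(res.success), message=res.message,
    )


def ec50_fold_change(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> float:
    """EC50 ratio a/b; > 1 means b responds at lower doses (more sensitive)."""
    if not (fit_a.converged and fit_b.converged):
        raise DomainError("fold change requires two converged fits")
    return fit_a.ec50 / fit_b.ec50


def _shared_ec50_residuals(theta, xa, ya, wa, xb, yb, wb):
    ba, ta, ha, bb, tb, hb, lec50 = theta
    ec50 = 10.0 ** lec50
    ra = wa * (four_pl(xa, ba, ta, ec50, ha) - ya)
    rb = wb * (four_pl(xb, bb, tb, ec50, hb) - yb)
    return np.concatenate([ra, rb])


def compare_ec50_f_test(doses_a, responses_a, doses_b, responses_b):
    """Extra-sum-of-squares F test for a common EC50 between two datasets.

    Full model: separate 4PL per dataset (8 parameters).  Null model: shared
    ec50, separate bottom/top/hill (7 parameters); Δdf = 1.  Returns
    (F, df1, df2, p_value).
    """
    xa, ya = np.asarray(doses_a, float), np.asarray(responses_a, float)
    xb, yb = np.asarray(doses_b, float), np.asarray(responses_b, float)
    fit_a = fit_4pl(xa, ya)
    fit_b = fit_4pl(xb, yb)
    if not (fit_a.converged and fit_b.converged):
        raise DomainError("F test requires both individual fits to converge")
    rss_full = fit_a.rss + fit_b.rss
    df_full = len(xa) + len(xb) - 8
    if df_full <= 0:
        raise DomainError("not enough points for the full (8-parameter) model")

    wa, wb = np.ones_like(ya), np.ones_like(yb)
    la, lb = _lec50_bounds(xa), _lec50_bounds(xb)
    llo, lhi = min(la[0], lb[0]), max(la[1], lb[1])
    lower = np.array([-np.inf, -np.inf, HILL_BOUNDS[0]] * 2 + [llo])
    upper = np.array([np.inf, np.inf, HILL_BOUNDS[1]] * 2 + [lhi])
    # start the null fit from each individual fit's ec50 and their log-midpoint
    lec50_starts = np.unique(np.clip(
        [np.log10(fit_a.ec50), np.log10(fit_b.ec50),
         0.5 * (np.log10(fit_a.ec50) + np.log10(fit_b.ec50))], llo, lhi))
    rss_null = np.inf
    for l0 in lec50_starts:
        theta0 = np.array([
            fit_a.bottom, fit_a.top, np.clip(fit_a.hill, *HILL_BOUNDS),
            fit_b.bottom, fit_b.top, np.clip(fit_b.hill, *HILL_BOUNDS),
            l0,
        ])
        res = optimize.least_squares(
            _shared_ec50_residuals, theta0, args=(xa, ya, wa, xb, yb, wb),
            bounds=(lower, upper), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        rss_null = min(rss_null, float(2.0 * res.cost))

    df1 = 1
    extra = max(rss_null - rss_full, 0.0)
    if rss_full <= 0:
        # noiseless data: identical curves give F = 0, different ones F -> inf
        if extra <= 1e-12 * max(rss_null, 1.0):
            return 0.0, df1, df_full, 1.0
        return float("inf"), df1, df_full, 0.0
    f_stat = (extra / df1) / (rss_full / df_full)
    p = float(stats.f.sf(f_stat, df1, df_full))
    return float(f_stat), df1, df_full, p


def dose_response_points(dataset, response: str = "geometric_mean"):
    """Per-dose summary responses for curve fitting.

    ``geometric_mean`` back-transforms a log10-scale dataset to the linear
    geometric mean per dose (10**mean(log10 y)); ``mean`` averages on the
    dataset's transformed scale.
    """
    means = np.array([y.mean() for y in dataset.outputs_per_dose])
    if response == "geometric_mean":
        if dataset.transform_tag.startswith("log10"):
            return dataset.doses.copy(), 10.0 ** means
        return dataset.doses.copy(), np.array(
            [np.exp(np.log(np.asarray(y)[np.asarray(y) > 0]).mean())
             for y in dataset.outputs_per_dose]
        )
    if response == "mean":
        return dataset.doses.copy(), means
    raise DomainError(f"unknown response summary {response!r}")
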