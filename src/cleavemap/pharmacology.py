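"""Dose-response fitting, time-series AUC and relative bioavailability.

The dose-response model is the three-parameter logistic with Hill slope
fixed at 1:

    E(c) = baseline + (emax - baseline) / (1 + ec50 / c)

fitted by least squares on the log-concentration scale (a four-parameter
variant with a free Hill slope is available behind a flag).  Exposure is
summarized by the trapezoidal rule over the observed sampling window only
— no back-extrapolation to t=0 and no terminal-phase extrapolation — and
relative bioavailability is the dose-normalized AUC ratio

    F_rel = (AUC_oral / AUC_inj) * (Dose_inj / Dose_oral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseDataset",
    "DoseResponseFit",
    "PKSeries",
    "fit_three_parameter_logistic",
    "trapezoid_auc",
    "relative_bioavailability",
]


@dataclass(frozen=True)
class DoseResponseDataset:
    """Paired concentration (nM, > 0) and response observations.

    Replicates are represented by repeated concentrations; fitting needs
    at least 4 distinct concentrations.
    """

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(c <= 0):
            raise ValueError("all concentrations must be > 0")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    @property
    def n_distinct(self) -> int:
        return np.unique(self.concentrations).size


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted logistic parameters with standard errors and a convergence flag."""

    ec50: float
    emax: float
    baseline: float
    hill: float = 1.0
    se: dict = field(default_factory=dict)
    converged: bool = True


def _logistic3(logc: np.ndarray, baseline: float, emax: float, log_ec50: float) -> np.ndarray:
    return baseline + (emax - baseline) / (1.0 + np.exp(log_ec50 - logc))


def _logistic4(
    logc: np.ndarray, baseline: float, emax: float, log_ec50: float, hill: float
) -> np.ndarray:
    return baseline + (emax - baseline) / (1.0 + np.exp(hill * (log_ec50 - logc)))


def fit_three_parameter_logistic(
    data: DoseResponseDataset, free_hill: bool = False
) -> DoseResponseFit:
    """Least-squares fit of the logistic dose-response curve.

    Initialization: baseline = min response, emax = max response, EC50 =
    geometric mean concentration.  Non-convergence (including a degenerate
    flat response) is flagged on the result, never raised silently.
    """
    if data.n_distinct < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations, got {data.n_distinct}"
        )
    logc = np.log(data.concentrations)
    y = data.responses
    p0 = [float(y.min()), float(y.max()), float(logc.mean())]
    if free_hill:
        p0.append(1.0)
    model = _logistic4 if free_hill else _logistic3
    if np.ptp(y) == 0:
        return DoseResponseFit(
            ec50=float(np.exp(logc.mean())), emax=float(y[0]), baseline=float(y[0]),
            converged=False,
        )
    try:
        popt, pcov = curve_fit(model, logc, y, p0=p0, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(perr)))
    except RuntimeError:
        return DoseResponseFit(
            ec50=float(np.exp(p0[2])), emax=p0[1], baseline=p0[0], converged=False
        )
    names = ["baseline", "emax", "log_ec50"] + (["hill"] if free_hill else [])
    se = dict(zip(names, perr))
    # delta method for EC50 on the natural scale
    se["ec50"] = float(np.exp(popt[2]) * se["log_ec50"])
    return DoseResponseFit(
        ec50=float(np.exp(popt[2])),
        emax=float(popt[1]),
        baseline=float(popt[0]),
        hill=float(popt[3]) if free_hill else 1.0,
        se=se,
        converged=converged,
    )


def trapezoid_auc(times, values) -> float:
    """Trapezoidal AUC over the observed window (no extrapolation).

    Units are value x time; times must be strictly increasing with at
    least two points.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.shape != v.shape:
        raise ValueError("need >= 2 paired (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


@dataclass(frozen=True)
class PKSeries:
    """A concentration-time profile with its route label and dose."""

    times: np.ndarray  # hours
    concentrations: np.ndarray  # ng/mL
    route: str = ""  # e.g. "SI" (subcutaneous injection) or "OG" (oral gavage)
    dose: float | None = None  # mg/kg

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def auc(self) -> float:
        """Exposure (ng*h/mL) by the trapezoidal rule."""
        return trapezoid_auc(self.times, self.concentrations)


def relative_bioavailability(
    auc_oral: float, auc_si: float, dose_si: float, dose_oral: float
) -> float:
    """Dose-normalized oral-vs-injected exposure ratio (a fraction).

    F_rel = (AUC_oral / AUC_inj) * (Dose_inj / Dose_oral); multiply by 100
    for a percentage.
    """
    for name, val in (
        ("auc_oral", auc_oral), ("auc_si", auc_si),
        ("dose_si", dose_si), ("dose_oral", dose_oral),
    ):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    return (auc_oral / auc_si) * (dose_si / dose_oral)
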