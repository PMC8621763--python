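"""Nonlinear (lognormal sigmoid) dose-response model for noncancer risk.

The probability of occurrence of an adverse health effect (PrHE) for a
lifetime average daily dose is modelled as the cumulative lognormal
distribution of toxicological susceptibility across the population: a dose
equal to the effective dose ED50 produces a 50% response, and the spread of
the response in log10-dose units is ``sigma_log`` (central tendency 0.26).

Because the model depends only on the ratio of dose to ED50, every function
here takes the dose expressed as a *fraction of ED50* (unitless).  In closed
form::

    PrHE(x) = Phi(log10(x) / sigma_log)

where ``Phi`` is the standard normal CDF.  The closed form is exact: the
lognormal density in dose integrates to the normal CDF in log10-dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DomainError

__all__ = [
    "DEFAULT_SIGMA_LOG",
    "DoseResponseCurve",
    "prhe_nonlinear",
    "log10_prhe_nonlinear",
    "prhe_inverse",
    "prhe_derivative",
    "fraction_of_ed50",
]

#: Central tendency of the spread of log10 toxicological susceptibility.
DEFAULT_SIGMA_LOG = 0.26

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Parameters of the lognormal sigmoid dose-response model.

    Parameters
    ----------
    sigma_log
        Spread of log10 toxicological susceptibility (unitless, > 0).
    ed50_ingestion, ed50_inhalation
        Optional route-specific effective doses (mg/kg bodyweight/d),
        needed only when converting absolute doses to ED50 fractions.
    """

    sigma_log: float = DEFAULT_SIGMA_LOG
    ed50_ingestion: float | None = None
    ed50_inhalation: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_log) and self.sigma_log > 0):
            raise ConfigurationError(
                f"sigma_log must be finite and > 0, got {self.sigma_log!r}"
            )
        for route in ("ed50_ingestion", "ed50_inhalation"):
            value = getattr(self, route)
            if value is not None and not (np.isfinite(value) and value > 0):
                raise ConfigurationError(
                    f"{route} must be finite and > 0 when given, got {value!r}"
                )


def _check_fraction(x: float) -> float:
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise DomainError(f"dose fraction must be finite and >= 0, got {x!r}")
    return x


def prhe_nonlinear(x: float, curve: DoseResponseCurve | None = None) -> float:
    """Probability of a health effect at dose fraction ``x`` (= X/ED50).

    Returns ``Phi(log10(x)/sigma_log)``; 0 at ``x = 0`` (continuity limit),
    0.5 at ``x = 1`` by the definition of ED50.
    """
    curve = curve or DoseResponseCurve()
    x = _check_fraction(x)
    if x == 0.0:
        return 0.0
    return float(norm.cdf(math.log10(x) / curve.sigma_log))


def log10_prhe_nonlinear(x: float, curve: DoseResponseCurve | None = None) -> float:
    """log10 of PrHE, evaluated in the log tail so that magnitudes far below
    the smallest representable double remain meaningful.

    Returns ``-inf`` at ``x = 0``.
    """
    curve = curve or DoseResponseCurve()
    x = _check_fraction(x)
    if x == 0.0:
        return -math.inf
    return float(norm.logcdf(math.log10(x) / curve.sigma_log)) / _LN10


def prhe_inverse(p: float, curve: DoseResponseCurve | None = None) -> float:
    """Dose fraction at which the model yields probability ``p``.

    Closed-form inverse ``10**(sigma_log * Phi^-1(p))``; round-trips with
    :func:`prhe_nonlinear` to machine precision.
    """
    curve = curve or DoseResponseCurve()
    p = float(p)
    if not (0.0 < p < 1.0):
        raise DomainError(f"probability must lie strictly in (0, 1), got {p!r}")
    return float(10.0 ** (curve.sigma_log * norm.ppf(p)))


def prhe_derivative(x: float, curve: DoseResponseCurve | None = None) -> float:
    """Marginal slope d(PrHE)/dx of the nonlinear curve at dose fraction x.

    Equals ``phi(log10(x)/sigma_log) / (sigma_log * x * ln 10)`` with ``phi``
    the standard normal density; strictly positive for every x > 0.
    """
    curve = curve or DoseResponseCurve()
    x = float(x)
    if not np.isfinite(x) or x <= 0:
        raise DomainError(f"dose fraction must be finite and > 0, got {x!r}")
    z = math.log10(x) / curve.sigma_log
    return float(norm.pdf(z)) / (curve.sigma_log * x * _LN10)


def fraction_of_ed50(dose: float, ed50: float) -> float:
    """Express an average daily dose (mg/kg/d) as a fraction of ED50."""
    dose = float(dose)
    ed50 = float(ed50)
    if not np.isfinite(ed50) or ed50 <= 0:
        raise DomainError(f"ed50 must be finite and > 0, got {ed50!r}")
    if not np.isfinite(dose) or dose < 0:
        raise DomainError(f"dose must be finite and >= 0, got {dose!r}")
    return dose / ed50
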