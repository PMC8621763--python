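"""Interval segmentation of the sigmoid dose-response curve.

The working risk range runs from a negligible-risk floor (PrHE = 1e-6 by
default) up to the ED10 anchor (PrHE = 10%).  Within that range the curve is
split into intervals by an iterative tangent construction: launch the tangent
line at the current interval's start; the interval ends at the first dose
where the nonlinear curve exceeds the tangent line by a configurable
discrepancy factor (5 by default, reflecting the typical magnitude of
uncertainty factors in toxicity assessment).  Each interval is then replaced
by its *secant* — the straight line through its two endpoint values — which,
by convexity of the curve over this span, never under-predicts risk.

The resulting table of segments (base dose X0, slope S, base probability R0)
is the piecewise-linear stand-in for the nonlinear model::

    PrHE(X) = S * (X - X0) + R0        for X in the segment's span
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dose_response import (
    DoseResponseCurve,
    prhe_derivative,
    prhe_inverse,
    prhe_nonlinear,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "SegmentationConfig",
    "LinearSegment",
    "SegmentTable",
    "find_boundaries",
    "build_secant_table",
    "build_segment_table",
    "evaluate_piecewise",
    "ed10_linear_prhe",
    "max_relative_difference",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _interval_label(index: int) -> str:
    return _ROMAN[index] if index < len(_ROMAN) else str(index + 1)


@dataclass(frozen=True)
class SegmentationConfig:
    """Configuration of the interval-finding procedure.

    ``p_min``/``p_max`` bound the working risk range (defaults 1e-6 and 10%,
    i.e. negligible risk up to ED10); ``discrepancy_factor`` is the
    nonlinear-to-tangent ratio that terminates an interval.
    """

    p_min: float = 1e-6
    p_max: float = 0.10
    discrepancy_factor: float = 5.0
    sigma_log: float = 0.26

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max < 0.5):
            raise ConfigurationError(
                "require 0 < p_min < p_max < 0.5, got "
                f"p_min={self.p_min!r}, p_max={self.p_max!r}"
            )
        if not self.discrepancy_factor > 1.0:
            raise ConfigurationError(
                f"discrepancy_factor must be > 1, got {self.discrepancy_factor!r}"
            )
        if not self.sigma_log > 0:
            raise ConfigurationError(
                f"sigma_log must be > 0, got {self.sigma_log!r}"
            )

    @property
    def curve(self) -> DoseResponseCurve:
        return DoseResponseCurve(sigma_log=self.sigma_log)


@dataclass(frozen=True)
class LinearSegment:
    """One linearized interval: PrHE(X) = slope * (X - x_start) + base_prhe."""

    x_start: float
    x_end: float
    slope: float
    base_prhe: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_start < self.x_end):
            raise DomainError(
                f"require 0 <= x_start < x_end, got ({self.x_start}, {self.x_end})"
            )

    def __call__(self, x: float) -> float:
        return self.slope * (x - self.x_start) + self.base_prhe

    @property
    def end_prhe(self) -> float:
        return self(self.x_end)


@dataclass(frozen=True)
class SegmentTable:
    """Ordered, contiguous collection of linear segments covering
    [0, x(p_max)], with the configuration that produced it."""

    segments: tuple[LinearSegment, ...]
    config: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("segment table must contain at least one segment")
        for left, right in zip(self.segments, self.segments[1:]):
            if not np.isclose(left.x_end, right.x_start, rtol=0, atol=1e-12):
                raise DomainError(
                    f"segments not contiguous at {left.x_end} vs {right.x_start}"
                )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def x_max(self) -> float:
        return self.segments[-1].x_end

    def segment_for(self, x: float) -> LinearSegment:
        """Segment whose half-open span (x_start, x_end] contains x > 0."""
        for seg in self.segments:
            if seg.x_start < x <= seg.x_end:
                return seg
        raise DomainError(f"x={x!r} outside table span (0, {self.x_max}]")

    # -- serialization ----------------------------------------------------

    def to_records(self) -> list[dict]:
        return [
            {
                "interval_label": seg.label,
                "x_start": seg.x_start,
                "x_end": seg.x_end,
                "slope": seg.slope,
                "base_prhe": seg.base_prhe,
            }
            for seg in self.segments
        ]

    def to_json(self) -> str:
        payload = {
            "config": {
                "p_min": self.config.p_min,
                "p_max": self.config.p_max,
                "discrepancy_factor": self.config.discrepancy_factor,
                "sigma_log": self.config.sigma_log,
            },
            "segments": self.to_records(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SegmentTable":
        payload = json.loads(text)
        config = SegmentationConfig(**payload["config"])
        segments = tuple(
            LinearSegment(
                x_start=rec["x_start"],
                x_end=rec["x_end"],
                slope=rec["slope"],
                base_prhe=rec["base_prhe"],
                label=rec.get("interval_label", ""),
            )
            for rec in payload["segments"]
        )
        return cls(segments=segments, config=config)


def find_boundaries(
    config: SegmentationConfig | None = None, *, xtol: float = 1e-12
) -> list[float]:
    """Interval boundaries of the tangent-launch segmentation.

    Starting at x1 = x(p_min) — the tangent cannot be launched at 0, where
    every derivative of the curve vanishes — repeatedly find the smallest
    x beyond the launch point at which the nonlinear curve exceeds the
    tangent line by ``discrepancy_factor``; that x launches the next
    interval.  The iteration stops when the factor is no longer attained
    before x(p_max); the final boundary is x(p_max) itself.

    Returns the ordered boundary list, ending with x(p_max).
    """
    config = config or SegmentationConfig()
    curve = config.curve
    x_max = prhe_inverse(config.p_max, curve)
    factor = config.discrepancy_factor

    boundaries: list[float] = []
    x_k = prhe_inverse(config.p_min, curve)
    # Bounded by x_max shrinkage each step; cap guards against pathological
    # configs where intervals contract too slowly to ever reach x_max.
    for _ in range(10_000):
        slope = prhe_derivative(x_k, curve)
        y_k = prhe_nonlinear(x_k, curve)

        def ratio_excess(x: float) -> float:
            tangent = y_k + slope * (x - x_k)
            return prhe_nonlinear(x, curve) / tangent - factor

        if ratio_excess(x_max) < 0.0:
            boundaries.append(x_max)
            return boundaries
        lo = x_k * (1.0 + 1e-9)
        if ratio_excess(lo) >= 0.0:  # pragma: no cover - defensive
            raise RuntimeError(
                f"cannot bracket discrepancy root above x={x_k!r}: "
                "ratio already exceeds the factor at the launch point"
            )
        b = float(brentq(ratio_excess, lo, x_max, xtol=xtol))
        boundaries.append(b)
        x_k = b
    raise RuntimeError(
        "segmentation did not terminate within 10000 intervals"
    )  # pragma: no cover


def build_secant_table(
    boundaries: list[float], config: SegmentationConfig | None = None
) -> SegmentTable:
    """Secant-based piecewise-linear table over the given boundaries.

    The first segment is anchored at the origin (x_start = 0, base 0) so
    the whole exposure range is covered; every later segment k runs between
    consecutive boundaries with the secant slope
    ``[PrHE(b_k) - PrHE(b_{k-1})] / (b_k - b_{k-1})``.
    """
    config = config or SegmentationConfig()
    curve = config.curve
    if not boundaries:
        raise DomainError("boundaries must be non-empty")
    arr = np.asarray(boundaries, dtype=float)
    if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
        raise DomainError(f"boundaries must be positive and increasing: {boundaries}")

    segments = []
    x_prev, p_prev = 0.0, 0.0
    for i, b in enumerate(arr):
        p_b = prhe_nonlinear(float(b), curve)
        segments.append(
            LinearSegment(
                x_start=x_prev,
                x_end=float(b),
                slope=(p_b - p_prev) / (float(b) - x_prev),
                base_prhe=p_prev,
                label=_interval_label(i),
            )
        )
        x_prev, p_prev = float(b), p_b
    return SegmentTable(segments=tuple(segments), config=config)


def build_segment_table(config: SegmentationConfig | None = None) -> SegmentTable:
    """Convenience: run the full segmentation and return the secant table."""
    config = config or SegmentationConfig()
    return build_secant_table(find_boundaries(config), config)


def evaluate_piecewise(x: float, table: SegmentTable) -> float:
    """Piecewise-linear PrHE at dose fraction x.

    Interval membership is half-open (x_start, x_end]; x = 0 returns 0.
    Beyond the table's range the linearization no longer applies (it was
    built only up to the ED10 anchor), so the nonlinear model is used
    instead and a warning is emitted.
    """
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise DomainError(f"dose fraction must be finite and >= 0, got {x!r}")
    if x == 0.0:
        return 0.0
    if x > table.x_max:
        warnings.warn(
            f"dose fraction {x:g} exceeds the linearized range "
            f"(0, {table.x_max:g}]; falling back to the nonlinear model",
            stacklevel=2,
        )
        return prhe_nonlinear(x, table.config.curve)
    return table.segment_for(x)(x)


def ed10_linear_prhe(x: float, config: SegmentationConfig | None = None) -> float:
    """Single fixed-slope estimate through the ED10 point.

    The straight line from the origin through (x(p_max), p_max) — the
    conventional one-slope linear extrapolation this package's interval
    table is meant to improve on.
    """
    config = config or SegmentationConfig()
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise DomainError(f"dose fraction must be finite and >= 0, got {x!r}")
    x_ed10 = prhe_inverse(config.p_max, config.curve)
    return x * config.p_max / x_ed10


def max_relative_difference(
    segment: LinearSegment,
    curve: DoseResponseCurve | None = None,
    *,
    n_grid: int = 10_001,
) -> float:
    """Largest percent over-prediction of a segment's secant vs the curve.

    Returns ``max over the span of 100 * (linear - nonlinear)/nonlinear``,
    located by dense grid search plus bounded local refinement.  Within the
    convex span the secant lies above the curve, so the value is >= 0.  For
    a segment anchored at the origin the ratio diverges as x -> 0; the grid
    then starts just above 0 and the reported maximum reflects that growth.
    """
    curve = curve or DoseResponseCurve()
    if segment.x_end == segment.x_start:
        return 0.0
    lo = segment.x_start if segment.x_start > 0 else segment.x_end * 1e-6
    xs = np.linspace(lo, segment.x_end, n_grid)

    def pct_diff(x: float) -> float:
        nl = prhe_nonlinear(float(x), curve)
        return 100.0 * (segment(float(x)) - nl) / nl

    vals = np.array([pct_diff(x) for x in xs])
    i = int(np.argmax(vals))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, len(xs) - 1)]
    res = minimize_scalar(lambda x: -pct_diff(x), bounds=(a, b), method="bounded")
    return float(max(vals[i], -res.fun))
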