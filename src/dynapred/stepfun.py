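"""Right-continuous step functions (cumulative-hazard and survival curves)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function defined by knots and post-knot values.

    ``f(t) = value_before`` for ``t < knots[0]`` and ``f(t) = values[k]`` for
    ``knots[k] <= t < knots[k+1]``. Evaluation is vectorized.
    """

    knots: np.ndarray
    values: np.ndarray
    value_before: float = 0.0

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.ndim != 1 or values.ndim != 1 or knots.shape != values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            out = np.full_like(t, self.value_before)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.knots, t, side=side) - 1
        out = np.where(
            idx < 0, self.value_before, self.values[np.clip(idx, 0, None)]
        )
        return out if out.ndim else float(out)

    def __call__(self, t):
        return self._eval(t, "right")

    def left_limit(self, t):
        """Evaluate ``f(t-)``, the left-continuous version."""
        return self._eval(t, "left")

    @property
    def last_knot(self) -> float:
        return float(self.knots[-1]) if self.knots.size else -np.inf

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "values": self.values.tolist(),
            "value_before": self.value_before,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepFunction":
        return cls(
            np.asarray(d["knots"], dtype=float),
            np.asarray(d["values"], dtype=float),
            float(d.get("value_before", 0.0)),
        )
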