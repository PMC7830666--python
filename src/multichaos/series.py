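"""The scalar time-series container shared by every stage of the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .errors import ParameterError

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, finite, real-valued scalar series with a sampling period.

    Parameters
    ----------
    values : array-like of float
        The samples, in signal units (dimensionless for maps, seconds for
        R-R interval series).
    dt : float
        Sampling period in seconds per step. For iterated maps and for
        beat-indexed R-R series this is 1.0, so rates come out "per step"
        ("per beat" for R-R data).
    meta : mapping, optional
        Free-form provenance labels (system name, parameters, seed, units...).
    """

    values: np.ndarray
    dt: float = 1.0
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ParameterError("a TimeSeries needs a non-empty 1-D value array")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("TimeSeries values must all be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ParameterError(f"dt must be a positive finite number, got {self.dt}")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total spanned time in seconds: (N - 1) * dt."""
        return (len(self) - 1) * self.dt

    def with_values(self, values: np.ndarray, **meta: Any) -> "TimeSeries":
        """A copy carrying new values, the same dt, and updated meta labels."""
        return replace(self, values=np.asarray(values, dtype=float),
                       meta={**self.meta, **meta})

    def truncate(self, n: int) -> "TimeSeries":
        """The first ``n`` samples (all of them if the series is shorter)."""
        if n < 1:
            raise ParameterError("truncation length must be >= 1")
        if n >= len(self):
            return self
        return self.with_values(self.values[:n], truncated_to=n)
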