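"""Exponential-moving-average smoothing and last-k slope estimation.

The controller's two trigger signals are trends: the slope of the GFP MFI
series (a sustained decline marks biosensor adaptation) and the slope of the
%PI series (a rise marks viability loss).  Both series are smoothed with an
EMA to suppress single-sample outliers, and the slope is the ordinary
least-squares slope of the last ``k`` smoothed values against their actual
acquisition times, so skipped (unusable) samples and irregular intervals are
handled naturally.

With fewer than ``k`` points the slope is *undefined* — a value, not an
error — and the controller takes no action on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OrderingError, ValidationError


@dataclass
class TrendSeries:
    """One smoothed statistic time series.

    Parameters
    ----------
    alpha : float
        EMA weight in (0, 1]; ``ema_new = alpha*x + (1-alpha)*ema_prev``.
        Default 0.5, the span-3 convention ``alpha = 2/(k+1)`` matched to the
        three-point slope window.
    k : int
        Slope window length in samples, default 3.
    slope_on : str
        Fit the slope to the ``ema`` values (default) or to ``raw``.
    """

    alpha: float = 0.5
    k: int = 3
    slope_on: str = "ema"
    times: list = field(default_factory=list)
    raw: list = field(default_factory=list)
    ema: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
        if self.k < 2:
            raise ValidationError("slope window k must be >= 2")
        if self.slope_on not in ("ema", "raw"):
            raise ValidationError(f"unknown slope_on {self.slope_on!r}")
        if not (len(self.times) == len(self.raw) == len(self.ema)):
            raise ValidationError("times/raw/ema must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def append(self, t: float, x: float) -> "TrendSeries":
        """Append one observation; the first value passes through unchanged."""
        if not np.isfinite(x):
            raise ValidationError(f"non-finite value {x!r} at t={t}")
        if self.times and t <= self.times[-1]:
            raise OrderingError(
                f"time {t} not after previous sample at {self.times[-1]}")
        self.times.append(float(t))
        self.raw.append(float(x))
        if len(self.ema) == 0:
            self.ema.append(float(x))
        else:
            self.ema.append(self.alpha * x + (1.0 - self.alpha) * self.ema[-1])
        return self

    @property
    def last_ema(self) -> float | None:
        return self.ema[-1] if self.ema else None

    def slope_last_k(self) -> float | None:
        """OLS slope of the last ``k`` (smoothed) values vs time, per hour.

        Returns ``None`` while fewer than ``k`` points exist.
        """
        if len(self.times) < self.k:
            return None
        t = np.asarray(self.times[-self.k:])
        src = self.ema if self.slope_on == "ema" else self.raw
        v = np.asarray(src[-self.k:])
        t_c = t - t.mean()
        return float(t_c @ (v - v.mean()) / (t_c @ t_c))


def ema_append(series: TrendSeries, t: float, x: float) -> TrendSeries:
    """Functional alias for :meth:`TrendSeries.append` (mutates ``series``)."""
    return series.append(t, x)


def slope_last_k(series: TrendSeries) -> float | None:
    """Alias for :meth:`TrendSeries.slope_last_k`."""
    return series.slope_last_k()
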