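"""Cumulative distributions used by the skilled-birth-attendance risk model.

Two input distributions drive the model:

* ``OnsetDistribution`` — the CDF ``F`` of the labour-onset offset
  ADD − EDD (actual minus expected delivery date), in **days**; negative
  values mean labour started before the due date.
* ``LatentPhaseDistribution`` — the parity-specific CDF ``Gk`` of the
  latent-phase duration, in **hours**, supported on non-negative values.

Both wrap an arbitrary monotone CDF callable restricted to a closed
support interval; outside the support the CDF is clamped to 0/1.  The
onset distribution additionally honours the "no MWH stay" sentinel
``NO_MWH`` (``d = +inf``), at which ``F`` is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: Sentinel move date meaning "no stay at a maternity waiting home".
NO_MWH: float = math.inf

Parity = Literal["nulliparous", "multiparous"]
PARITIES: tuple[Parity, Parity] = ("nulliparous", "multiparous")


def _validate_parity(parity: str) -> Parity:
    if parity not in PARITIES:
        raise ValueError(f"unknown parity {parity!r}; expected one of {PARITIES}")
    return parity  # type: ignore[return-value]


@dataclass(frozen=True)
class CdfDistribution:
    """A distribution known through its CDF on a closed support interval.

    Parameters
    ----------
    cdf_callable
        Vectorised monotone map from the support to [0, 1].  It is
        evaluated only inside the support; it need not itself clamp.
    support
        Closed interval ``(lo, hi)``.  Below ``lo`` the CDF is 0, above
        ``hi`` it is 1.
    source
        Free-form provenance tag, e.g. ``"kde"``, ``"surrogate"`` or a
        preset name.
    """

    cdf_callable: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    support: tuple[float, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not lo < hi:
            raise ValueError(f"support must satisfy lo < hi, got {self.support}")

    def cdf(self, x) -> float | np.ndarray:
        """Evaluate the CDF, total on the reals (plus the +inf sentinel)."""
        scalar = np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.support
        out = np.empty(x.shape, dtype=float)
        inside = (x >= lo) & (x <= hi)
        out[x < lo] = 0.0
        out[x > hi] = 1.0  # covers the +inf sentinel exactly
        if inside.any():
            out[inside] = np.clip(self.cdf_callable(x[inside]), 0.0, 1.0)
        return float(out[0]) if scalar else out

    def quantile(self, p: float) -> float:
        """Invert the CDF by bisection: the smallest x with cdf(x) >= p."""
        if not 0.0 < p < 1.0:
            raise ValueError(f"quantile level must lie in (0, 1), got {p}")
        lo, hi = self.support
        if self.cdf(lo) >= p:
            return lo
        if self.cdf(hi) <= p:
            return hi
        return brentq(lambda x: self.cdf(x) - p, lo, hi, xtol=1e-9)


@dataclass(frozen=True)
class OnsetDistribution(CdfDistribution):
    """CDF ``F`` of the labour-onset offset ADD − EDD, in days.

    ``cdf(NO_MWH)`` is exactly 1, encoding ``F(+inf) = 1`` for a woman
    who does not plan an MWH stay.
    """


@dataclass(frozen=True)
class LatentPhaseDistribution(CdfDistribution):
    """Parity-specific CDF ``Gk`` of the latent-phase duration, in hours."""

    parity: Parity = "nulliparous"

    def __post_init__(self) -> None:
        super().__post_init__()
        _validate_parity(self.parity)
        lo, _ = self.support
        if lo < 0:
            raise ValueError("latent-phase durations are non-negative; support must start at >= 0")


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    """Read an empirical sample file.

    Expected dialect: UTF-8 CSV with a header, one numeric column named
    ``value`` (onset offsets in days, or latent durations in hours) and
    an optional ``parity`` column for latent-phase files.
    """
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column, found {list(df.columns)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if "parity" in df.columns:
        for p in df["parity"].unique():
            _validate_parity(str(p))
    return df
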