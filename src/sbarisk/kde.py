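"""Gaussian kernel density estimation on a truncated support.

The model's input CDFs are estimated from empirical samples with a
Gaussian KDE whose bandwidth is, by default, a *factor* applied to the
sample SD (``h = bandwidth_factor * sd(samples)``, the common scalar
parameterisation); an absolute bandwidth in data units is available via
``bandwidth_mode="absolute"``.  Mass falling outside the stated value
range is clipped and the density renormalised over the range, so the
estimated CDF is exactly 0 at the lower and 1 at the upper bound.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.special import ndtr

from .distributions import LatentPhaseDistribution, OnsetDistribution, Parity

__all__ = ["kde_estimate", "DEFAULT_BANDWIDTH_FACTOR"]

#: Default multiplicative bandwidth (times the sample SD).
DEFAULT_BANDWIDTH_FACTOR = 0.3


def kde_estimate(
    samples,
    bandwidth_factor: float = DEFAULT_BANDWIDTH_FACTOR,
    support: tuple[float, float] = (-30.0, 30.0),
    *,
    parity: Parity | None = None,
    bandwidth_mode: Literal["relative", "absolute"] = "relative",
    source: str = "kde",
) -> OnsetDistribution | LatentPhaseDistribution:
    """Estimate a distribution by truncated Gaussian KDE.

    Parameters
    ----------
    samples
        Empirical values (onset offsets in days, or latent durations in
        hours).  At least two distinct values are required.
    bandwidth_factor
        Kernel SD as a multiple of the sample SD (``"relative"`` mode,
        default) or directly in data units (``"absolute"`` mode).
    support
        Value range; samples outside it are an error, and the density
        is renormalised over it.
    parity
        If given, the result is a :class:`LatentPhaseDistribution` for
        that parity; otherwise an :class:`OnsetDistribution`.

    Returns
    -------
    A distribution whose CDF is the renormalised equal-weight sum of
    Gaussian-kernel CDFs centred at the samples.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 samples for a KDE, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("samples must be finite")
    lo, hi = support
    if not lo < hi:
        raise ValueError(f"support must satisfy lo < hi, got {support}")
    if (x < lo).any() or (x > hi).any():
        bad = x[(x < lo) | (x > hi)]
        raise ValueError(
            f"{bad.size} sample(s) outside the support {support}; e.g. {bad[0]!r}"
        )
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth must be positive")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero sample variance: KDE would degenerate to a point mass")
    h = bandwidth_factor * sd if bandwidth_mode == "relative" else float(bandwidth_factor)

    # Raw (untruncated) mixture-of-kernels CDF, then renormalised over
    # [lo, hi] so that cdf(lo) = 0 and cdf(hi) = 1.
    z_lo = float(ndtr((lo - x) / h).mean())
    z_hi = float(ndtr((hi - x) / h).mean())
    mass = z_hi - z_lo
    if mass <= 0:
        raise ValueError("no kernel mass inside the support")
    centres, bw = x.copy(), h

    def cdf_callable(q: np.ndarray) -> np.ndarray:
        raw = ndtr((q[:, None] - centres[None, :]) / bw).mean(axis=1)
        return (raw - z_lo) / mass

    if parity is None:
        return OnsetDistribution(cdf_callable=cdf_callable, support=(lo, hi), source=source)
    return LatentPhaseDistribution(
        cdf_callable=cdf_callable, support=(lo, hi), source=source, parity=parity
    )
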