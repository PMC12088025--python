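"""Built-in cohort presets and their calibrated surrogate mixtures.

The registry (``data/presets.yaml``) records the published summary
statistics of the source cohorts:

* ``khambalia`` — labour-onset offsets ADD − EDD from 10,243 spontaneous
  singleton births (mean −1.48 d, SD 9.21 d, ~66% within ±7 d of EDD);
* ``mongelli`` — onset offsets from 34,249 pregnancies (mean −1.79 d,
  SD 11.3 d);
* ``friedman_nulliparous`` / ``friedman_multiparous`` — latent-phase
  durations from 500 labours per parity (means 7.1 h / 5.3 h, SDs
  4.0 h / 4.1 h, 95th percentiles 20 h / 14 h).

Each preset's surrogate mixture is calibrated on first access and the
constraint fit is re-verified (1e-3 relative, by quadrature) at that
point, so a registry entry that cannot be honoured fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Literal

import yaml

from .distributions import LatentPhaseDistribution, OnsetDistribution, Parity
from .mixtures import CalibrationSpec, TruncatedNormalMixture, calibrate_mixture

__all__ = [
    "CohortPreset",
    "available_presets",
    "get_preset",
    "onset_distribution",
    "latent_distribution",
]


@dataclass(frozen=True)
class CohortPreset:
    """A named cohort: its calibration spec, surrogate mixture and sizes."""

    name: str
    kind: Literal["onset", "latent"]
    parity: Parity | None
    spec: CalibrationSpec
    mixture: TruncatedNormalMixture
    kde_support: tuple[float, float]
    default_n: int

    def distribution(self) -> OnsetDistribution | LatentPhaseDistribution:
        """The surrogate CDF wrapped as a model input distribution."""
        if self.kind == "onset":
            return OnsetDistribution(
                cdf_callable=self.mixture.cdf, support=self.mixture.support, source=self.name
            )
        return LatentPhaseDistribution(
            cdf_callable=self.mixture.cdf,
            support=self.mixture.support,
            source=self.name,
            parity=self.parity,
        )


@lru_cache(maxsize=1)
def _registry_raw() -> dict:
    text = resources.files("sbarisk").joinpath("data/presets.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    return tuple(_registry_raw())


@lru_cache(maxsize=None)
def get_preset(name: str) -> CohortPreset:
    """Look up a preset by name, calibrating its surrogate mixture."""
    raw = _registry_raw()
    if name not in raw:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(raw)}")
    entry = raw[name]
    mass = entry.get("interval_mass")
    quant = entry.get("quantile")
    shape = entry.get("shape_points")
    spec = CalibrationSpec(
        target_mean=float(entry["mean"]),
        target_sd=float(entry["sd"]),
        support=tuple(entry["support"]),
        n_components=int(entry["n_components"]),
        target_interval_mass=(mass["lo"], mass["hi"], mass["mass"]) if mass else None,
        target_quantile=(quant["level"], quant["value"]) if quant else None,
        shape_points=tuple((float(x), float(c)) for x, c in shape) if shape else None,
    )
    mixture = calibrate_mixture(spec)  # raises CalibrationError if unsatisfiable
    return CohortPreset(
        name=name,
        kind=entry["kind"],
        parity=entry.get("parity"),
        spec=spec,
        mixture=mixture,
        kde_support=tuple(entry.get("kde_support", entry["support"])),
        default_n=int(entry["default_n"]),
    )


def onset_distribution(name: str = "khambalia") -> OnsetDistribution:
    """Surrogate labour-onset distribution F for an onset preset."""
    preset = get_preset(name)
    if preset.kind != "onset":
        raise ValueError(f"preset {name!r} is not an onset cohort")
    return preset.distribution()


def latent_distribution(parity: Parity, name: str | None = None) -> LatentPhaseDistribution:
    """Surrogate latent-phase distribution Gk for a parity.

    With no explicit ``name`` the Friedman preset for that parity is used.
    """
    if name is None:
        name = f"friedman_{parity}"
    preset = get_preset(name)
    if preset.kind != "latent":
        raise ValueError(f"preset {name!r} is not a latent-phase cohort")
    if preset.parity != parity:
        raise ValueError(f"preset {name!r} is for {preset.parity} women, not {parity}")
    return preset.distribution()
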