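"""Tissue compositions, photon attenuation, electron ranges, HU-to-density.

All tables ship as JSON inside ``ludose/data``.  Mass attenuation
coefficients of a compound follow the mixture rule (mass-fraction-weighted
sum of elemental coefficients) and are interpolated log-log in energy.
The HU-to-density curve is a monotone piecewise-linear calibration in the
stoichiometric (Schneider-type) style, anchored at water (HU 0 -> 1 g/cm^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "TissueComposition",
    "AttenuationTable",
    "HUDensityTable",
    "load_tissue",
    "load_attenuation",
    "load_hu_density",
    "hu_to_density",
    "density_to_hu",
    "mu_lookup",
    "electron_csda_range",
]

INTERACTIONS = ("photoelectric", "incoherent", "coherent")


def _read(name: str) -> dict:
    return json.loads(resources.files("ludose.data").joinpath(name).read_text())


@dataclass(frozen=True)
class TissueComposition:
    name: str
    mass_fractions: dict[str, float]
    density_g_cm3: float

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be > 0")


@lru_cache(maxsize=None)
def load_tissue(name: str) -> TissueComposition:
    raw = _read("tissues.json")[name]
    return TissueComposition(name, dict(raw["mass_fractions"]), raw["density_g_cm3"])


class AttenuationTable:
    """Elemental photon cross sections plus the electron CSDA range table."""

    def __init__(self, raw: dict):
        self.energy_kev = np.asarray(raw["energy_kev"], dtype=float)
        self._log_e = np.log(self.energy_kev)
        self.elements = {
            sym: {k: np.asarray(el[k], dtype=float) for k in INTERACTIONS}
            for sym, el in raw["elements"].items()
        }
        er = raw["electron_csda_range"]
        self._er_log_e = np.log(np.asarray(er["energy_kev"], dtype=float))
        self._er_log_r = np.log(np.asarray(er["range_g_cm2"], dtype=float))

    def material_mu_rho(self, material: TissueComposition) -> dict[str, np.ndarray]:
        """Per-interaction mu/rho (cm^2/g) of a compound on the energy grid."""
        out = {k: np.zeros_like(self.energy_kev) for k in INTERACTIONS}
        for sym, w in material.mass_fractions.items():
            el = self.elements[sym]
            for k in INTERACTIONS:
                out[k] += w * el[k]
        out["total"] = sum(out[k] for k in INTERACTIONS)
        return out

    def mu_lookup(self, material: TissueComposition, energy_kev: float) -> dict[str, float]:
        """Log-log interpolated mass attenuation coefficients at one energy."""
        e = float(energy_kev)
        if not (self.energy_kev[0] <= e <= self.energy_kev[-1]):
            raise ValueError(
                f"energy {e} keV outside table range "
                f"[{self.energy_kev[0]}, {self.energy_kev[-1]}]"
            )
        grids = self.material_mu_rho(material)
        loge = np.log(e)
        return {
            k: float(np.exp(np.interp(loge, self._log_e, np.log(v))))
            for k, v in grids.items()
        }

    def electron_csda_range(self, energy_kev) -> np.ndarray:
        """CSDA range in g/cm^2, log-log interpolated (clamped at table ends)."""
        loge = np.log(np.clip(np.asarray(energy_kev, dtype=float), 1e-3, None))
        return np.exp(np.interp(loge, self._er_log_e, self._er_log_r))


@lru_cache(maxsize=1)
def load_attenuation() -> AttenuationTable:
    return AttenuationTable(_read("attenuation.json"))


def mu_lookup(material: TissueComposition, energy_kev: float) -> dict[str, float]:
    return load_attenuation().mu_lookup(material, energy_kev)


def electron_csda_range(energy_kev):
    return load_attenuation().electron_csda_range(energy_kev)


class HUDensityTable:
    """Monotone piecewise-linear HU -> mass density conversion."""

    def __init__(self, breakpoints: list[tuple[float, float]]):
        pts = sorted((float(h), float(d)) for h, d in breakpoints)
        self.hu = np.array([p[0] for p in pts])
        self.density = np.array([p[1] for p in pts])
        if np.any(np.diff(self.density) < 0) or np.any(self.density < 0):
            raise ValueError("density must be non-negative and non-decreasing in HU")

    def to_density(self, hu):
        """Density in g/cm^3; values clamped to the table ends."""
        return np.interp(np.asarray(hu, dtype=float), self.hu, self.density)

    def to_hu(self, density):
        """Inverse of :meth:`to_density` (the curve is strictly increasing)."""
        return np.interp(np.asarray(density, dtype=float), self.density, self.hu)


@lru_cache(maxsize=1)
def load_hu_density() -> HUDensityTable:
    raw = _read("hu_density.json")
    return HUDensityTable([tuple(p) for p in raw["breakpoints_hu_density"]])


def hu_to_density(hu):
    """Convert HU (scalar or array) to mass density in g/cm^3."""
    return load_hu_density().to_density(hu)


def density_to_hu(density):
    """Convert mass density in g/cm^3 back to HU."""
    return load_hu_density().to_hu(density)
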