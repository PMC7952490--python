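"""Lu-177 emission data and decay sampling.

The emission model keeps three beta branches, the gamma/x-ray lines with
yield >= 0.1 % and lumped conversion/Auger electron lines, which together
carry essentially all of the emitted energy.  Beta branch spectra follow
the Fermi shape with the non-relativistic Coulomb correction and are
sampled by inverse-CDF lookup on a fine energy grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import ELECTRON_REST_KEV, FINE_STRUCTURE

__all__ = [
    "BetaBranch",
    "EmissionSpectrum",
    "load_lu177",
    "beta_spectrum_pdf",
    "sample_decay",
]


@dataclass(frozen=True)
class BetaBranch:
    endpoint_kev: float
    yield_per_decay: float
    daughter_z: int


def beta_spectrum_pdf(endpoint_kev: float, daughter_z: int, e_kev: np.ndarray) -> np.ndarray:
    """Unnormalised beta- spectrum N(E) on the kinetic-energy grid ``e_kev``.

    Allowed Fermi shape p * E_tot * (Q - E)^2 * F(Z, E) with the
    relativistic point-Coulomb Fermi function

        F = 2 (1 + g) (2 p R)^(2g - 2) exp(pi eta) |Gamma(g + i eta)|^2
            / Gamma(2g + 1)^2,

    g = sqrt(1 - (alpha Z)^2), eta = + alpha Z E_tot / p, and R the nuclear
    radius in Compton units.
    """
    from scipy.special import gammaln, loggamma

    e = np.asarray(e_kev, dtype=float)
    out = np.zeros_like(e)
    ok = (e > 0) & (e < endpoint_kev)
    etot = e[ok] + ELECTRON_REST_KEV
    p = np.sqrt(etot**2 - ELECTRON_REST_KEV**2)
    az = daughter_z * FINE_STRUCTURE
    g = np.sqrt(1.0 - az * az)
    eta = az * etot / p
    # nuclear radius R = 1.2 fm * A^(1/3) in units of the reduced electron
    # Compton wavelength (386.16 fm); A approximated from Z via A ~ 2.5 Z
    a_mass = 2.5 * daughter_z
    radius = 1.2 * a_mass ** (1.0 / 3.0) / 386.159
    log_gamma_term = 2.0 * np.real(loggamma(g + 1j * eta)) - 2.0 * gammaln(2 * g + 1.0)
    fermi = (
        2.0
        * (1.0 + g)
        * (2.0 * p / ELECTRON_REST_KEV * radius) ** (2.0 * g - 2.0)
        * np.exp(np.pi * eta + log_gamma_term)
    )
    out[ok] = p * etot * (endpoint_kev - e[ok]) ** 2 * fermi
    return out


def _branch_tables(branch: BetaBranch, grid_kev: float = 1.0, n_icdf: int = 1024):
    """Mean energy and inverse-CDF table (on a uniform u-grid) of a branch."""
    e = np.append(np.arange(0.0, branch.endpoint_kev, grid_kev), branch.endpoint_kev)
    pdf = beta_spectrum_pdf(branch.endpoint_kev, branch.daughter_z, e)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(e))])
    mean = np.trapezoid(pdf * e, e) / np.trapezoid(pdf, e)
    cdf /= cdf[-1]
    u = np.linspace(0.0, 1.0, n_icdf)
    # cdf is strictly increasing in the interior; np.interp handles ties at 0
    icdf = np.interp(u, cdf, e)
    return float(mean), icdf


@dataclass
class EmissionSpectrum:
    """Discrete emissions of one nuclide with per-decay yields."""

    photon_lines: list[tuple[float, float]]
    electron_lines: list[tuple[float, float]]
    beta_branches: list[BetaBranch]
    name: str = "Lu-177"
    half_life_h: float = 6.647 * 24.0
    reference_mean_electron_kev: float | None = None
    reference_mean_photon_kev: float | None = None
    _beta_means: list[float] = field(default_factory=list, repr=False)
    _beta_icdf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for e, y in self.photon_lines + self.electron_lines:
            if e <= 0 or y < 0:
                raise ValueError("emission lines need energy > 0 and yield >= 0")
        means, icdfs = [], []
        for br in self.beta_branches:
            m, icdf = _branch_tables(br)
            means.append(m)
            icdfs.append(icdf)
        self._beta_means = means
        self._beta_icdf = np.array(icdfs) if icdfs else np.empty((0, 1024))

    @property
    def mean_electron_energy(self) -> float:
        """Mean electron energy emitted per decay, keV."""
        disc = sum(e * y for e, y in self.electron_lines)
        beta = sum(m * br.yield_per_decay for m, br in zip(self._beta_means, self.beta_branches))
        return disc + beta

    @property
    def mean_photon_energy(self) -> float:
        """Mean photon energy emitted per decay, keV."""
        return sum(e * y for e, y in self.photon_lines)

    @property
    def mean_total_energy(self) -> float:
        return self.mean_electron_energy + self.mean_photon_energy

    def beta_icdf_tables(self) -> np.ndarray:
        """(n_branches, n_u) inverse-CDF tables for uniform u in [0, 1]."""
        return self._beta_icdf

    def without_photons(self) -> "EmissionSpectrum":
        """Copy with all photon yields removed (electron-only source)."""
        return EmissionSpectrum(
            photon_lines=[],
            electron_lines=list(self.electron_lines),
            beta_branches=list(self.beta_branches),
            name=self.name + " (electrons only)",
            half_life_h=self.half_life_h,
        )

    def as_arrays(self):
        """Plain float64 arrays for the transport kernels."""
        pe = np.array([e for e, _ in self.photon_lines], dtype=float)
        py = np.array([y for _, y in self.photon_lines], dtype=float)
        ee = np.array([e for e, _ in self.electron_lines], dtype=float)
        ey = np.array([y for _, y in self.electron_lines], dtype=float)
        by = np.array([br.yield_per_decay for br in self.beta_branches], dtype=float)
        return pe, py, ee, ey, by, np.asarray(self._beta_icdf, dtype=float)


def load_lu177() -> EmissionSpectrum:
    """Load the packaged Lu-177 emission table."""
    raw = json.loads(resources.files("ludose.data").joinpath("lu177_decay.json").read_text())
    return EmissionSpectrum(
        photon_lines=[tuple(x) for x in raw["photon_lines_kev_yield"]],
        electron_lines=[tuple(x) for x in raw["electron_lines_kev_yield"]],
        beta_branches=[BetaBranch(*b) for b in raw["beta_branches"]],
        name=raw["nuclide"],
        half_life_h=raw["half_life_days"] * 24.0,
        reference_mean_electron_kev=raw["reference_mean_electron_kev"],
        reference_mean_photon_kev=raw["reference_mean_photon_kev"],
    )


def _isotropic(rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2 * np.pi)
    s = np.sqrt(1.0 - z * z)
    return np.array([s * np.cos(phi), s * np.sin(phi), z])


def sample_decay(spectrum: EmissionSpectrum, rng: np.random.Generator):
    """Sample the emissions of one decay.

    Returns a list of ``(kind, energy_kev, direction)`` with kind in
    {"photon", "electron"}.  Yields above 1 are treated as expected
    multiplicities (integer part emitted always, fractional part Bernoulli).
    """
    out = []
    for kind, lines in (("photon", spectrum.photon_lines), ("electron", spectrum.electron_lines)):
        for e, y in lines:
            n = int(y) + (1 if rng.random() < y - int(y) else 0)
            for _ in range(n):
                out.append((kind, e, _isotropic(rng)))
    icdf = spectrum.beta_icdf_tables()
    for i, br in enumerate(spectrum.beta_branches):
        if rng.random() < br.yield_per_decay:
            u = rng.random() * (icdf.shape[1] - 1)
            j = min(int(u), icdf.shape[1] - 2)
            e = icdf[i, j] + (u - j) * (icdf[i, j + 1] - icdf[i, j])
            out.append(("electron", e, _isotropic(rng)))
    return out
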