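"""Convert resolved emitter profiles into absolute cross sections sigma(E).

The chain implemented here undoes, step by step, everything that stands
between a per-isotope Cherenkov amplitude profile a_i(z) and the production
cross section:

  1. activation build-up:  R_i(z) proportional to a_i(z) lambda_i /
     [yield_i (1 - exp(-lambda_i t_irr))]  — faster decayers need more
     production to sustain the same end-of-irradiation amplitude;
  2. geometry and flux:    sigma_rel(E(z)) = R_i(z) / (n_O Phi(z) dz);
  3. depth -> energy:      through the slowing-down map, with the Bohr
     straggling width attached as the per-point energy resolution;
  4. absolute scale:       one global factor fixed by matching the 15O curve
     maximum to an archival anchor value; the same factor is applied to all
     isotopes, and the anchor's relative uncertainty enters every point in
     quadrature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nuclides import DecayComponent
from .physics import EnergyDepthMap, Material, flux_attenuation

__all__ = [
    "CrossSectionTable",
    "Anchor",
    "quadratic_peak",
    "amplitudes_to_production",
    "to_energy_axis",
    "normalize_to_anchor",
]

log = logging.getLogger(__name__)


@dataclass
class CrossSectionTable:
    """Per-isotope sigma(E) with one-sigma uncertainties on both axes.

    Units are MeV / mbarn once absolute; relative (unnormalised) tables use
    the same container with meta['relative'] = True.
    """

    isotope: str
    energy: np.ndarray
    energy_unc: np.ndarray
    sigma: np.ndarray
    sigma_unc: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.energy_unc = np.asarray(self.energy_unc, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.sigma_unc = np.asarray(self.sigma_unc, dtype=float)
        n = len(self.energy)
        if not (len(self.energy_unc) == len(self.sigma) == len(self.sigma_unc) == n):
            raise ValueError("column length mismatch")
        if n == 0:
            raise ValueError("empty cross-section table")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if np.any(self.energy_unc < 0) or np.any(self.sigma_unc < 0):
            raise ValueError("uncertainties must be nonnegative")

    def __len__(self) -> int:
        return len(self.energy)

    def interpolate(self, energy: float | np.ndarray):
        """Linear sigma interpolation, zero outside the tabulated range."""
        s = np.interp(energy, self.energy, self.sigma, left=0.0, right=0.0)
        return float(s) if np.isscalar(energy) else s

    def peak(self) -> tuple[float, float]:
        """(energy, sigma) of the maximum, quadratic-interpolated."""
        return quadratic_peak(self.energy, self.sigma)

    def scaled(self, factor: float, extra_rel_unc: float = 0.0) -> "CrossSectionTable":
        sigma = self.sigma * factor
        unc = np.hypot(self.sigma_unc * factor, sigma * extra_rel_unc)
        meta = dict(self.meta)
        meta.pop("relative", None)
        return CrossSectionTable(self.isotope, self.energy.copy(), self.energy_unc.copy(),
                                 sigma, unc, meta)


def quadratic_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Parabolic interpolation of the maximum through the discrete argmax and
    its neighbours; robust to the grid step, falls back to the raw argmax at
    the array ends or on degenerate curvature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        i = int(np.argmax(y))
        return float(x[i]), float(y[i])
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    if a >= 0:
        return float(x1), float(y1)
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    xp = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    return float(xp), float(a * xp**2 + b * xp + c)


def _saturation_factor(decay_constant: float, t_irr: float) -> float:
    """1 - exp(-lambda t_irr), series-safe for small lambda t_irr."""
    return float(-np.expm1(-decay_constant * t_irr))


def amplitudes_to_production(
    amplitude: np.ndarray,
    amplitude_sigma: np.ndarray,
    component: DecayComponent,
    yield_factor: float,
    t_irr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the activation build-up: relative production rate per depth bin.

    R_i(z) propto a_i(z) * lambda_i / (yield_i * (1 - exp(-lambda_i t_irr))).
    The amplitude is referenced to t = 0 at end of irradiation, matching the
    decomposition's basis convention.
    """
    if yield_factor <= 0:
        raise ValueError("yield factor must be positive")
    if t_irr <= 0:
        raise ValueError("irradiation duration must be positive")
    lam = component.decay_constant
    sat = _saturation_factor(lam, t_irr)
    scale = lam / (yield_factor * sat)
    return np.asarray(amplitude, float) * scale, np.asarray(amplitude_sigma, float) * scale


def to_energy_axis(
    production: np.ndarray,
    production_sigma: np.ndarray,
    emap: EnergyDepthMap,
    material: Material,
    isotope: str,
    removal_cross_section_barn: float | None = None,
    energy_range: tuple[float, float] = (5.0, 70.0),
    mask: np.ndarray | None = None,
) -> CrossSectionTable:
    """Relative sigma(E) points from a production-rate depth profile.

    sigma_rel(E(z)) = R(z) / (n_O Phi(z) dz); each point carries the Bohr
    straggling width at its depth as the energy uncertainty.  Bins past the
    Bragg peak (non-invertible part of the map) and outside the requested
    energy range are dropped with a logged count.
    """
    r = np.asarray(production, dtype=float)
    rs = np.asarray(production_sigma, dtype=float)
    if r.shape != emap.depth_grid.shape:
        raise ValueError("production profile does not match the depth grid")
    n_o = material.oxygen_number_density
    if n_o <= 0:
        raise ValueError(f"material {material.name} contains no oxygen")
    phi = flux_attenuation(material, emap.depth_grid, removal_cross_section_barn)
    e = emap.energy_at_depth
    keep = (e > 0) & (e >= energy_range[0]) & (e <= energy_range[1]) & np.isfinite(r)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("to_energy_axis: dropped %d depth bins (out of range/masked)", n_drop)
    denom = n_o * phi[keep] * emap.depth_step
    sigma = r[keep] / denom
    sigma_unc = rs[keep] / denom
    order = np.argsort(e[keep])
    return CrossSectionTable(
        isotope=isotope,
        energy=e[keep][order],
        energy_unc=emap.straggling_sigma[keep][order],
        sigma=np.clip(sigma[order], 0.0, None),
        sigma_unc=sigma_unc[order],
        meta={"relative": True, "dropped_bins": n_drop},
    )


@dataclass(frozen=True)
class Anchor:
    """Archival absolute normalization point: the 15O curve maximum."""

    isotope: str = "15O"
    energy: float = 35.0        # MeV
    sigma: float = 76.8         # mbarn
    rel_uncertainty: float = 0.0245

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.rel_uncertainty < 0:
            raise ValueError("invalid anchor values")


def normalize_to_anchor(
    tables: dict[str, CrossSectionTable],
    anchor: Anchor = Anchor(),
) -> dict[str, CrossSectionTable]:
    """Set the one free scale of the relative curves from the archival anchor.

    The anchor isotope's quadratic-interpolated maximum is matched to the
    anchor value; because the camera's scale is common to all isotopes, the
    SAME factor converts every table, and the anchor's relative uncertainty
    is added to each point in quadrature.
    """
    if anchor.isotope not in tables:
        raise KeyError(f"anchor isotope {anchor.isotope} missing from tables")
    ref = tables[anchor.isotope]
    if np.all(ref.sigma == 0):
        raise ValueError("anchor isotope's relative curve is identically zero")
    e_peak, s_peak = ref.peak()
    if s_peak <= 0:
        raise ValueError("anchor isotope's relative curve has no positive maximum")
    if abs(e_peak - anchor.energy) > 2.0:
        warnings.warn(
            f"relative {anchor.isotope} maximum at {e_peak:.1f} MeV is more than "
            f"2 MeV from the anchor energy {anchor.energy} MeV",
            stacklevel=2,
        )
    factor = anchor.sigma / s_peak
    out = {}
    for iso, tab in tables.items():
        scaled = tab.scaled(factor, extra_rel_unc=anchor.rel_uncertainty)
        scaled.meta.update(anchor_isotope=anchor.isotope, anchor_energy=anchor.energy,
                           anchor_sigma=anchor.sigma, scale_factor=factor)
        out[iso] = scaled
    return out
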