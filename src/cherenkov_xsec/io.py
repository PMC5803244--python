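"""File formats and run configuration.

All profile and table data live in greppable TSV; image stacks are
multi-frame 16-bit TIFF with a JSON sidecar carrying the acquisition
metadata (frame times, exposure, pixel pitch, seed, config hash) needed to
regenerate or reanalyse them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .extraction import Anchor, CrossSectionTable
from .nuclides import DecayComponent
from .physics import BeamSpec, Material, get_material
from .preprocess import DepthProfileSeries
from .synthetic import CCDConfig

__all__ = [
    "read_xsec_table",
    "write_xsec_table",
    "read_series",
    "write_series",
    "read_stack",
    "write_stack",
    "read_amplitudes",
    "write_amplitudes",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# Cross-section tables (energy  denergy  sigma  dsigma)
# ---------------------------------------------------------------------------

def write_xsec_table(table: CrossSectionTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# isotope: {table.isotope}\n")
        for k, v in sorted(table.meta.items()):
            fh.write(f"# {k}: {v}\n")
        fh.write("energy\tdenergy\tsigma\tdsigma\n")
        for row in zip(table.energy, table.energy_unc, table.sigma, table.sigma_unc):
            fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")


def read_xsec_table(path: str | Path, isotope: Optional[str] = None) -> CrossSectionTable:
    """Parse a per-isotope sigma(E) TSV; malformed rows are rejected with
    their line numbers, non-monotone energies and empty tables are errors."""
    path = Path(path)
    meta: dict[str, Any] = {}
    rows: list[tuple[float, float, float, float]] = []
    header_seen = False
    bad: list[int] = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if not header_seen:
                if [p.strip() for p in parts[:4]] != ["energy", "denergy", "sigma", "dsigma"]:
                    raise ValueError(
                        f"{path}:{ln}: expected header 'energy denergy sigma dsigma'"
                    )
                header_seen = True
                continue
            try:
                vals = tuple(float(p) for p in parts)
                if len(vals) != 4:
                    raise ValueError
                rows.append(vals)
            except ValueError:
                bad.append(ln)
    if bad:
        raise ValueError(f"{path}: malformed rows at lines {bad}")
    if not rows:
        raise ValueError(f"{path}: empty cross-section table")
    arr = np.array(rows)
    iso = isotope or meta.pop("isotope", None) or path.stem
    return CrossSectionTable(
        isotope=iso, energy=arr[:, 0], energy_unc=arr[:, 1],
        sigma=arr[:, 2], sigma_unc=arr[:, 3], meta=meta,
    )


# ---------------------------------------------------------------------------
# Depth-profile series (long TSV: depth  time  intensity  variance  mask)
# ---------------------------------------------------------------------------

def write_series(series: DepthProfileSeries, path: str | Path) -> None:
    nd, nf = series.intensity.shape
    depth = np.repeat(series.depth_grid, nf)
    time = np.tile(series.frame_times, nd)
    mask = np.repeat(series.mask.astype(int), nf)
    df = pd.DataFrame({
        "depth": depth,
        "time": time,
        "intensity": series.intensity.ravel(),
        "variance": series.variance.ravel(),
        "mask": mask,
    })
    with Path(path).open("w") as fh:
        fh.write(f"# exposure: {series.exposure}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_series(path: str | Path) -> DepthProfileSeries:
    path = Path(path)
    exposure = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# exposure:"):
            exposure = float(first.split(":", 1)[1])
    if exposure is None:
        raise ValueError(f"{path}: missing '# exposure:' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    depth = np.unique(df["depth"].to_numpy())
    times = np.unique(df["time"].to_numpy())
    nd, nf = len(depth), len(times)
    if len(df) != nd * nf:
        raise ValueError(f"{path}: not a complete depth x time grid")
    df = df.sort_values(["depth", "time"])
    return DepthProfileSeries(
        depth_grid=depth,
        frame_times=times,
        exposure=exposure,
        intensity=df["intensity"].to_numpy().reshape(nd, nf),
        variance=df["variance"].to_numpy().reshape(nd, nf),
        mask=df.groupby("depth", sort=True)["mask"].first().to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# Amplitude tables (depth  isotope  amplitude  sigma  chi2_dof  mask)
# ---------------------------------------------------------------------------

def write_amplitudes(resolved, chi2_dof: np.ndarray, path: str | Path) -> None:
    """Resolved per-isotope amplitude profiles in long TSV form."""
    records = []
    for iso, prof in resolved.profiles.items():
        for d, a, s, c2, m in zip(resolved.depth_grid, prof, resolved.sigmas[iso],
                                  chi2_dof, resolved.mask):
            records.append((d, iso, a, s, c2, int(m)))
    df = pd.DataFrame(records, columns=["depth", "isotope", "amplitude", "sigma",
                                        "chi2_dof", "mask"])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_amplitudes(path: str | Path):
    """Returns (depth_grid, {isotope: (amplitude, sigma)}, mask)."""
    df = pd.read_csv(path, sep="\t")
    depth = np.unique(df["depth"].to_numpy())
    out = {}
    mask = None
    for iso, sub in df.groupby("isotope"):
        sub = sub.sort_values("depth")
        out[iso] = (sub["amplitude"].to_numpy(), sub["sigma"].to_numpy())
        mask = sub["mask"].to_numpy().astype(bool)
    return depth, out, mask


# ---------------------------------------------------------------------------
# TIFF stacks + sidecar
# ---------------------------------------------------------------------------

def write_stack(stack, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    sidecar = {
        "frame_times": list(map(float, stack.frame_times)),
        "exposure": float(stack.exposure),
        "pixel_pitch": float(stack.pixel_pitch),
        "dark_level": float(stack.dark_level),
        "read_noise_sigma": float(stack.read_noise_sigma),
        "seed": stack.seed,
        "config_hash": config_hash,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    frames = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return frames, meta


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _default_components() -> list[dict]:
    from .constants import NUCLIDE_DATA

    return [dict(isotope=iso, **NUCLIDE_DATA[iso]) for iso in ("15O", "13N", "11C")]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to YAML losslessly."""

    material: dict = field(default_factory=lambda: {"name": "quartz"})
    beam: dict = field(default_factory=lambda: {
        "initial_energy": 72.0, "current_na": 30.0, "irradiation_duration": 1800.0,
        "lateral_fwhm": [0.400, 0.246],
    })
    ccd: dict = field(default_factory=lambda: {
        "pixel_pitch": 0.0133, "exposure": 5.0, "frame_start": 120.0,
        "frame_stop": 3600.0, "n_lateral": 32, "gain": 1.0,
        "read_noise_sigma": 10.0, "dark_level": 100.0,
    })
    components: list = field(default_factory=_default_components)
    fit_window: list = field(default_factory=lambda: [120.0, 3600.0])
    kernel_range_fraction: float = 0.5
    deconv_iterations: int = 50
    median_window: int = 3
    edge_min_depth: float = 0.12
    sample_length: float = 3.5
    anchor: dict = field(default_factory=lambda: {
        "isotope": "15O", "energy": 35.0, "sigma": 76.8, "rel_uncertainty": 0.0245,
    })
    seed: Optional[int] = None

    # -- construction helpers ------------------------------------------------
    def build_material(self) -> Material:
        d = dict(self.material)
        return get_material(d.pop("name"), **d)

    def build_beam(self) -> BeamSpec:
        d = dict(self.beam)
        d["lateral_fwhm"] = tuple(d.get("lateral_fwhm", (0.400, 0.246)))
        return BeamSpec(**d)

    def build_ccd(self) -> CCDConfig:
        d = dict(self.ccd)
        start = d.pop("frame_start", 120.0)
        stop = d.pop("frame_stop", 3600.0)
        exposure = d.get("exposure", 5.0)
        d["frame_times"] = np.arange(start, stop, exposure)
        return CCDConfig(**d)

    def build_components(self) -> list[DecayComponent]:
        return [DecayComponent(**c) for c in self.components]

    def build_anchor(self) -> Anchor:
        return Anchor(**self.anchor)

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
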