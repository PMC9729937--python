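"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators emulate the experimental readouts the analysis consumes,
so every downstream stage can be validated without wet-lab data:

* noisy replicate viability tables drawn around a known Hill curve;
* linear radial colony-expansion time series (colony radius grows at a
  constant rate, resistant lines slower than sensitive ones);
* two-channel colony images (all-cells "nuclei" + sensitive-only "marker")
  with a recorded ground-truth resistant fraction and footprint size.

The colony footprint is set by cell number at constant areal density, so
its diameter scales as sqrt(cell count) — consistent with the observed
jump of over 2x in initial diameter when seeding 50K instead of 10K cells.
Cells are rendered as anti-aliased constant-radius discs at uniformly
random positions (overlaps allowed); all randomness flows from the single
integer seed in the spec.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import HillParams, ViabilityTable, viability
from .imaging import ColonyImagePair

__all__ = [
    "SyntheticColonySpec",
    "GrowthCurveSpec",
    "make_viability_table",
    "make_growth_curves",
    "make_colony_image",
    "seeded_cell_count",
    "save_colony_pair",
]

GEOMETRIES = ("scattered", "subcolony_center", "subcolony_edge")

#: Fractional radial position of the sub-colony centre in "edge" geometry
#: (placed near, but inside, the colony boundary).
EDGE_OFFSET_FRACTION = 0.8


def seeded_cell_count(drop_volume_uL: float, density_per_mL: float) -> int:
    """Cells deposited by one seeding drop: volume (uL) x density (cells/mL).

    A 20 uL drop at 1e6 cells/mL seeds 20,000 cells.
    """
    if drop_volume_uL <= 0 or density_per_mL <= 0:
        raise ValueError("drop volume and density must be > 0")
    return int(round(drop_volume_uL * 1e-3 * density_per_mL))


def make_viability_table(
    params: HillParams,
    doses: Sequence[float],
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ViabilityTable:
    """Replicate viability readings V(dose) + N(0, noise_sd) per well.

    Deterministic given ``seed``; ``noise_sd = 0`` returns exact curve
    values.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose grid is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = viability(doses, params)
    mat = clean[:, None] + rng.normal(0.0, noise_sd, size=(doses.size, replicates))
    return ViabilityTable.from_replicates(doses, mat)


@dataclass(frozen=True)
class GrowthCurveSpec:
    """One colony's linear radial expansion: r(t) = r0 + rate * t + noise."""

    initial_radius_um: float
    expansion_rate_um_per_h: float
    timepoints_h: tuple
    noise_sd_um: float = 0.0
    seed: int = 0
    name: str = "colony"

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-empty and ascending")
        if self.initial_radius_um < 0 or self.noise_sd_um < 0:
            raise ValueError("initial radius and noise sd must be >= 0")


def make_growth_curves(specs: Sequence[GrowthCurveSpec]) -> pd.DataFrame:
    """Radius time series for a list of colonies (long-format table).

    Columns: ``colony, time_h, radius_um, floored``.  Negative expansion
    rates (shrinking colonies) are allowed; radii that would go negative
    are floored at 0 and flagged in the ``floored`` column with a warning.
    """
    frames = []
    for spec in specs:
        t = np.asarray(spec.timepoints_h, dtype=float)
        rng = np.random.default_rng(spec.seed)
        r = spec.initial_radius_um + spec.expansion_rate_um_per_h * t
        if spec.noise_sd_um > 0:
            r = r + rng.normal(0.0, spec.noise_sd_um, size=t.size)
        floored = r < 0
        if floored.any():
            warnings.warn(
                f"colony {spec.name!r}: {int(floored.sum())} radius value(s) "
                "floored at 0",
                stacklevel=2,
            )
            r = np.maximum(r, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "colony": spec.name,
                    "time_h": t,
                    "radius_um": r,
                    "floored": floored,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Recipe for one two-channel colony image with known composition.

    The footprint disc area is (n_sensitive + n_resistant) / areal_density;
    the recorded ground-truth resistant fraction is
    n_resistant / (n_sensitive + n_resistant).  Geometries: ``scattered``
    mixes both populations uniformly across the footprint;
    ``subcolony_center`` / ``subcolony_edge`` confine the resistant cells
    to a sub-disc (sized by ``subcolony_cell_count`` at the same areal
    density) at the centre or near the boundary.
    """

    n_cells_sensitive: int
    n_cells_resistant: int
    areal_density_per_mm2: float = 1500.0
    geometry: str = "scattered"
    subcolony_cell_count: Optional[int] = None
    cell_radius_um: float = 5.0
    pixel_size_um: float = 5.0
    image_shape: Optional[tuple] = None
    background_level: float = 100.0
    noise_sd: float = 5.0
    amplitude: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_sensitive < 0 or self.n_cells_resistant < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n_cells_sensitive + self.n_cells_resistant == 0:
            raise ValueError("colony must contain at least one cell")
        if self.areal_density_per_mm2 <= 0:
            raise ValueError("areal density must be > 0")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.cell_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("cell radius and pixel size must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_cells_sensitive + self.n_cells_resistant

    @property
    def fraction_resistant(self) -> float:
        return self.n_cells_resistant / self.n_total

    @property
    def footprint_area_mm2(self) -> float:
        return self.n_total / self.areal_density_per_mm2

    @property
    def footprint_radius_px(self) -> float:
        radius_mm = math.sqrt(self.footprint_area_mm2 / math.pi)
        return radius_mm * 1000.0 / self.pixel_size_um

    def resolved_shape(self) -> tuple:
        if self.image_shape is not None:
            return tuple(int(s) for s in self.image_shape)
        side = 2 * int(math.ceil(1.05 * self.footprint_radius_px)) + 32
        return (side, side)


def _uniform_disc(rng, n, center, radius):
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return np.column_stack(
        (center[0] + r * np.sin(theta), center[1] + r * np.cos(theta))
    )


def _render_discs(shape, centers, radius_px, amplitude):
    """Additively render anti-aliased discs at float pixel positions."""
    img = np.zeros(shape, dtype=np.float32)
    if len(centers) == 0:
        return img
    w = int(math.ceil(radius_px + 1.5))
    offs = np.arange(-w, w + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    cy = centers[:, 0]
    cx = centers[:, 1]
    by = np.round(cy).astype(np.int64)
    bx = np.round(cx).astype(np.int64)
    py = by[:, None, None] + oy[None]
    px = bx[:, None, None] + ox[None]
    dist = np.hypot(py - cy[:, None, None], px - cx[:, None, None])
    # coverage ramps linearly over the 1 px anti-aliasing band at the rim
    cov = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    ok = (py >= 0) & (py < shape[0]) & (px >= 0) & (px < shape[1]) & (cov > 0)
    np.add.at(img, (py[ok], px[ok]), (amplitude * cov[ok]).astype(np.float32))
    return img


def make_colony_image(spec: SyntheticColonySpec):
    """Render one colony as a (ColonyImagePair, ground-truth dict) pair.

    The nuclei channel shows every cell, the marker channel sensitive cells
    only.  Additive Gaussian background noise on a constant background
    level; 16-bit dynamic range.  Bit-identical for identical spec + seed.
    """
    shape = spec.resolved_shape()
    R = spec.footprint_radius_px
    center = (shape[0] / 2.0, shape[1] / 2.0)
    if R > min(center):
        raise ValueError(
            f"footprint radius {R:.1f} px exceeds image half-size {min(center):.1f}"
        )
    rng = np.random.default_rng(spec.seed)
    sens = _uniform_disc(rng, spec.n_cells_sensitive, center, R)
    if spec.geometry == "scattered":
        res = _uniform_disc(rng, spec.n_cells_resistant, center, R)
        sub = None
    else:
        n_sub = (
            spec.subcolony_cell_count
            if spec.subcolony_cell_count is not None
            else spec.n_cells_resistant
        )
        r_sub = R * math.sqrt(max(n_sub, 1) / spec.n_total)
        if spec.geometry == "subcolony_center":
            offset = 0.0
        else:
            offset = min(EDGE_OFFSET_FRACTION * R, R - r_sub)
        sub_center = (center[0], center[1] + offset)
        res = _uniform_disc(rng, spec.n_cells_resistant, sub_center, r_sub)
        sub = {"center_px": sub_center, "radius_px": r_sub}

    r_px = spec.cell_radius_um / spec.pixel_size_um
    all_cells = np.vstack((sens, res))
    nuclei = _render_discs(shape, all_cells, r_px, spec.amplitude)
    marker = _render_discs(shape, sens, r_px, spec.amplitude)

    def finish(signal):
        noisy = (
            signal
            + spec.background_level
            + rng.normal(0.0, spec.noise_sd, size=shape)
        )
        return np.clip(noisy, 0, 65535).astype(np.uint16)

    pair = ColonyImagePair(
        nuclei=finish(nuclei), marker=finish(marker), pixel_size_um=spec.pixel_size_um
    )
    ground_truth = {
        "fraction_resistant": spec.fraction_resistant,
        "n_cells_sensitive": spec.n_cells_sensitive,
        "n_cells_resistant": spec.n_cells_resistant,
        "footprint_area_mm2": spec.footprint_area_mm2,
        "footprint_diameter_um": 2.0
        * math.sqrt(spec.footprint_area_mm2 / math.pi)
        * 1000.0,
        "footprint_radius_px": R,
        "center_px": list(center),
        "subcolony": sub,
        "geometry": spec.geometry,
        "pixel_size_um": spec.pixel_size_um,
        "seed": spec.seed,
        "rng": "numpy.random.default_rng(PCG64)",
        # half the single-cell peak, above the noise floor: a sensible
        # batch threshold for images from this generator
        "threshold_hint": spec.background_level + spec.amplitude / 2.0,
    }
    return pair, ground_truth


def save_colony_pair(
    pair: ColonyImagePair,
    ground_truth: dict,
    outdir,
    stem: str = "colony",
    spec: Optional[SyntheticColonySpec] = None,
) -> dict:
    """Write 16-bit grayscale TIFFs (one per channel) plus a JSON sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclei": outdir / f"{stem}_nuclei.tif",
        "marker": outdir / f"{stem}_marker.tif",
        "sidecar": outdir / f"{stem}.json",
    }
    tifffile.imwrite(paths["nuclei"], pair.nuclei)
    tifffile.imwrite(paths["marker"], pair.marker)
    sidecar = {"ground_truth": ground_truth}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2, default=list)
    return {k: str(v) for k, v in paths.items()}
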