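"""Synthetic well images, plates and screen tables with exact ground truth.

The generator emulates what a high-content imager sees in the spheroid
migration assay: a compact dark spheroid core sitting in the middle of the
field, a halo of emigrated cell-sized blobs at configurable radial
distances from the core boundary, Hoechst signal on every nucleus, PI
signal on the membrane-compromised (dead) subset, and the artifacts that
the QC rules exist for (empty wells, two spheroids, a fiber crossing the
core, debris).  Every rendered object is recorded in a :class:`WellTruth`
so downstream segmentation and statistics can be validated against exact
ground truth.

Image model
-----------
Brightfield is bright background with dark objects; fluorescence channels
are dark background with bright objects.  Each object is assigned a focal
slice in the z-stack and rendered progressively dimmer and blurrier in
neighbouring slices — enough out-of-focus structure that an extended-focus
composite is meaningfully sharper than any single slice, without
pretending to model the optics (no PSF/shot-noise physics).

The numbers-only screen generator (:func:`generate_screen_table`) skips
images entirely: it draws per-well migration areas around planted fold
effects on the normalized scale, which is what the plate-statistics layer
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, LayoutError
from .imaging import ImageStack, PlateLayout, save_well

ARTIFACT_KINDS = ("empty_well", "two_spheroids", "fiber", "debris")


@dataclass(frozen=True)
class DistanceSpec:
    """Distribution of migration distances, μm from the core boundary.

    Families: ``gamma`` (shape, scale), ``exponential`` (scale),
    ``uniform`` (low, high), ``constant`` (value).
    """

    family: str = "gamma"
    params: tuple[float, ...] = (2.0, 40.0)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=n)
        if self.family == "exponential":
            (scale,) = self.params
            return rng.exponential(scale, size=n)
        if self.family == "uniform":
            low, high = self.params
            return rng.uniform(low, high, size=n)
        if self.family == "constant":
            (value,) = self.params
            return np.full(n, float(value))
        raise ConfigurationError(f"unknown distance family {self.family!r}")


@dataclass
class SynthParams:
    """Generator configuration for one well.

    Defaults reproduce the assay's acquisition geometry (nine optical
    sections, 25 μm apart) and calibrate the core-size distribution to the
    reported real-spheroid mean of 27,437 μm² (SD 1,073 μm²).  Pixel size
    defaults to 1 μm/px so areas in μm² equal pixel counts.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 1.0
    n_slices: int = 9
    z_interval: float = 25.0
    core_area_mean: float = 27437.0
    core_area_sd: float = 1073.0
    n_halo_cells: int = 150
    migration_distances: DistanceSpec = field(default_factory=DistanceSpec)
    dead_fraction: float = 0.2
    cell_radius: float = 6.0
    n_chains: int = 20
    noise_sd: float = 0.02
    artifact_probabilities: dict[str, float] = field(default_factory=dict)
    # rendering levels (intensities in [0, 1])
    bf_background: float = 0.80
    bf_core_level: float = 0.35
    bf_cell_depth: float = 0.35
    fluor_core_level: float = 0.65
    fluor_cell_peak: tuple[float, float] = (0.55, 0.9)

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ConfigurationError(f"bad image_shape {self.image_shape}")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if self.core_area_mean <= 0 or self.core_area_sd < 0:
            raise ConfigurationError("core area distribution must be positive")
        if not 0 <= self.dead_fraction <= 1:
            raise ConfigurationError("dead_fraction must be in [0, 1]")
        if self.n_chains < 0:
            raise ConfigurationError("n_chains must be >= 0")
        if self.n_halo_cells < 0 or self.cell_radius <= 0:
            raise ConfigurationError("bad halo-cell configuration")
        for kind, p in self.artifact_probabilities.items():
            if kind not in ARTIFACT_KINDS:
                raise ConfigurationError(f"unknown artifact kind {kind!r}")
            if not 0 <= p <= 1:
                raise ConfigurationError(f"artifact probability {kind}={p} out of [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "image_shape" in data:
            data["image_shape"] = tuple(data["image_shape"])
        if "migration_distances" in data:
            md = data["migration_distances"]
            data["migration_distances"] = DistanceSpec(
                md["family"], tuple(md["params"])
            )
        if "fluor_cell_peak" in data:
            data["fluor_cell_peak"] = tuple(data["fluor_cell_peak"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "image_shape": list(self.image_shape),
            "pixel_size": self.pixel_size,
            "n_slices": self.n_slices,
            "z_interval": self.z_interval,
            "core_area_mean": self.core_area_mean,
            "core_area_sd": self.core_area_sd,
            "n_halo_cells": self.n_halo_cells,
            "migration_distances": {
                "family": self.migration_distances.family,
                "params": list(self.migration_distances.params),
            },
            "dead_fraction": self.dead_fraction,
            "cell_radius": self.cell_radius,
            "n_chains": self.n_chains,
            "noise_sd": self.noise_sd,
            "artifact_probabilities": dict(self.artifact_probabilities),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass(frozen=True)
class CellRecord:
    """One emigrated cell: centroid (row, col) px, distance from the core
    boundary in μm, and whether it is alive (PI-negative)."""

    row: float
    col: float
    distance_um: float
    alive: bool


@dataclass
class WellTruth:
    """Exact ground truth for one generated well."""

    core_area: float  # μm², 0 when no spheroid
    core_centroid: tuple[float, float] | None  # (row, col) px
    n_spheroids: int
    cell_records: list[CellRecord] = field(default_factory=list)
    artifact_flags: set[str] = field(default_factory=set)
    planted_fold: float = 1.0
    second_core: tuple[float, float, float] | None = None  # (row, col, area μm²)
    # (aspect ratio, axis angle rad): a fiber stretches the spheroid itself
    core_elongation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_spheroids not in (0, 1, 2):
            raise ConfigurationError("n_spheroids must be in {0, 1, 2}")
        if any(c.distance_um < 0 for c in self.cell_records):
            raise ConfigurationError("truth distances must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.cell_records)

    @property
    def n_dead(self) -> int:
        return sum(not c.alive for c in self.cell_records)

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_px": [c.row for c in self.cell_records],
                "col_px": [c.col for c in self.cell_records],
                "distance_um": [c.distance_um for c in self.cell_records],
                "alive": [c.alive for c in self.cell_records],
            }
        )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _radial_alpha(shape, center, radius_px, edge_width, elongation=None):
    """Soft-edged disk: 1 inside, smooth sigmoid falloff at the boundary.

    ``elongation=(aspect, angle)`` stretches the disk into an equal-area
    ellipse with the major axis along ``angle``.
    """
    rr = np.arange(shape[0], dtype=np.float32)[:, None] - center[0]
    cc = np.arange(shape[1], dtype=np.float32)[None, :] - center[1]
    if elongation is not None:
        aspect, angle = elongation
        k = np.sqrt(aspect)
        major = (rr * np.sin(angle) + cc * np.cos(angle)) / k
        minor = (-rr * np.cos(angle) + cc * np.sin(angle)) * k
        r = np.sqrt(major * major + minor * minor)
    else:
        r = np.sqrt(rr * rr + cc * cc)
    z = np.clip((r - radius_px) / max(edge_width, 1e-3), -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(z))


def _add_blob(image, row, col, sigma, amplitude, sign=1.0):
    """Add a Gaussian blob into ``image`` in place (local patch only)."""
    half = max(int(np.ceil(3.0 * sigma)), 2)
    r0, r1 = int(row) - half, int(row) + half + 1
    c0, c1 = int(col) - half, int(col) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, image.shape[0]), min(c1, image.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c, dtype=np.float32)[:, None] - row
    cc = np.arange(c0c, c1c, dtype=np.float32)[None, :] - col
    blob = amplitude * np.exp(-(rr * rr + cc * cc) / (2.0 * sigma * sigma))
    image[r0c:r1c, c0c:c1c] += sign * blob


def _defocus(distance: int) -> tuple[float, float]:
    """(amplitude factor, width factor) for a slice ``distance`` away from focus."""
    return 1.0 / (1.0 + 0.7 * distance), 1.0 + 0.45 * distance


def _draw_truth(params: SynthParams, rng: np.random.Generator) -> WellTruth:
    """Sample everything stochastic about the well content (no pixels)."""
    flags: set[str] = set()
    probs = params.artifact_probabilities
    # fixed draw order over all artifact kinds keeps the stream stable
    for kind in ARTIFACT_KINDS:
        if rng.uniform() < probs.get(kind, 0.0):
            flags.add(kind)
    if "empty_well" in flags:
        flags &= {"empty_well", "debris"}  # an empty well cannot hold spheroids
        return WellTruth(0.0, None, 0, [], flags)

    shape = params.image_shape
    core_area = float(
        np.clip(
            rng.normal(params.core_area_mean, params.core_area_sd),
            25 * params.pixel_size**2,
            None,
        )
    )
    radius_px = np.sqrt(core_area / np.pi) / params.pixel_size
    elongation = None
    if "fiber" in flags:
        elongation = (float(rng.uniform(2.2, 2.8)), float(rng.uniform(0, np.pi)))
    jitter = 0.04 * min(shape)
    center = (
        shape[0] / 2 + rng.uniform(-jitter, jitter),
        shape[1] / 2 + rng.uniform(-jitter, jitter),
    )

    second = None
    n_spheroids = 1
    if "two_spheroids" in flags:
        area2 = float(
            np.clip(
                rng.normal(0.7 * params.core_area_mean, params.core_area_sd),
                25 * params.pixel_size**2,
                None,
            )
        )
        r2 = np.sqrt(area2 / np.pi) / params.pixel_size
        # among candidate directions, keep those with the most room so the
        # second body stays clearly separated even on small fields
        jitter_angle = rng.uniform(0, 2 * np.pi)
        best = None
        for k in range(16):
            theta = jitter_angle + k * np.pi / 8
            u = (np.sin(theta), np.cos(theta))
            t_max = np.inf
            for axis in (0, 1):
                lo, hi = r2 + 4, shape[axis] - r2 - 4
                if abs(u[axis]) > 1e-9:
                    t_lo = (lo - center[axis]) / u[axis]
                    t_hi = (hi - center[axis]) / u[axis]
                    t_max = min(t_max, max(t_lo, t_hi))
            if best is None or t_max > best[1]:
                best = (u, t_max)
        u, t_max = best
        gap = min(2.0 * (radius_px + r2), t_max)
        second = (
            float(center[0] + gap * u[0]),
            float(center[1] + gap * u[1]),
            area2,
        )
        n_spheroids = 2

    # halo cells: sampled radial distance from the core boundary
    cells: list[CellRecord] = []
    n = params.n_halo_cells
    if n > 0:
        dists_um = params.migration_distances.sample(rng, n)
        angles = rng.uniform(0, 2 * np.pi, size=n)
        alive = rng.uniform(size=n) >= params.dead_fraction
        margin = 2.0 * params.cell_radius / params.pixel_size + 2
        for d_um, th, al in zip(dists_um, angles, alive):
            rad = radius_px + d_um / params.pixel_size
            row = center[0] + rad * np.sin(th)
            col = center[1] + rad * np.cos(th)
            row = float(np.clip(row, margin, shape[0] - margin - 1))
            col = float(np.clip(col, margin, shape[1] - margin - 1))
            # truth distance re-derived from the final (possibly clipped) position
            d_final = max(
                (np.hypot(row - center[0], col - center[1]) - radius_px)
                * params.pixel_size,
                0.0,
            )
            cells.append(CellRecord(row, col, d_final, bool(al)))

    return WellTruth(
        core_area, center, n_spheroids, cells, flags, 1.0, second, elongation
    )


def _render_core(
    canvas: np.ndarray,
    params: SynthParams,
    center,
    area_um2: float,
    delta: float,
    focal: int,
    slice_idx: int,
    speckle: np.ndarray | None,
    elongation: tuple[float, float] | None = None,
):
    """Add a soft-edged disk: ``delta`` < 0 darkens (brightfield core),
    ``delta`` > 0 brightens (fluorescent core)."""
    radius_px = np.sqrt(area_um2 / np.pi) / params.pixel_size
    amp_f, width_f = _defocus(abs(slice_idx - focal))
    alpha = _radial_alpha(
        canvas.shape, center, radius_px, 1.2 * width_f, elongation
    )
    canvas += delta * amp_f * alpha
    if speckle is not None:
        canvas += speckle * alpha * amp_f


def _cell_sigma_px(params: SynthParams) -> float:
    return max(params.cell_radius / params.pixel_size / 1.5, 1.0)


def generate_well(
    params: SynthParams,
    seed: int | np.random.SeedSequence,
    channels: Sequence[str] = ("brightfield", "hoechst", "pi"),
) -> tuple[dict[str, ImageStack], WellTruth]:
    """Render one synthetic well and its exact ground truth.

    Deterministic for a given ``(params, seed)``; the truth draw is
    independent of which ``channels`` are rendered, so a brightfield-only
    render shares its truth with the full three-channel render.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    # fixed fan-out: truth, brightfield extras, fluorescence amps, then one
    # noise stream per channel — independent of which channels are rendered
    children = ss.spawn(6)
    rng_truth = np.random.default_rng(children[0])
    rng_bf = np.random.default_rng(children[1])
    rng_fluor = np.random.default_rng(children[2])
    noise_children = dict(zip(("brightfield", "hoechst", "pi"), children[3:6]))
    truth = _draw_truth(params, rng_truth)

    shape = params.image_shape
    n_slices = params.n_slices
    mid = n_slices // 2
    sigma_px = _cell_sigma_px(params)

    # per-object focal slices and fluorescence amplitudes (drawn channel-
    # independently so the rendering subset never shifts the stream)
    n_cells = truth.n_cells
    cell_focal = rng_truth.integers(0, n_slices, size=n_cells) if n_cells else []
    amp_lo, amp_hi = params.fluor_cell_peak
    cell_amp_h = rng_fluor.uniform(amp_lo, amp_hi, size=n_cells) if n_cells else []
    cell_amp_p = rng_fluor.uniform(amp_lo, amp_hi, size=n_cells) if n_cells else []

    # migration chains (brightfield only): radial strands rooted at the core
    # boundary whose lengths follow the migration-distance distribution, so
    # the contiguous object grows with migration the way collective/chain
    # migration does.  Angles are stratified (evenly spaced with jitter) so
    # chains never fuse into a solid collar around the core.
    chains: list[tuple[float, float]] = []  # (angle, length μm)
    if truth.core_centroid is not None and params.n_chains > 0 and n_cells > 0:
        n_ch = params.n_chains
        rotation = rng_bf.uniform(0, 2 * np.pi)
        jitter = rng_bf.uniform(-0.3, 0.3, size=n_ch)
        lengths = params.migration_distances.sample(rng_bf, n_ch)
        chains = [
            (rotation + (i + jitter[i]) * 2 * np.pi / n_ch, float(lengths[i]))
            for i in range(n_ch)
        ]

    speckle = None
    if truth.n_spheroids >= 1:
        speckle = rng_bf.uniform(-0.07, 0.07, size=shape).astype(np.float32)

    fiber = None
    if "fiber" in truth.artifact_flags and truth.core_centroid is not None:
        # the fiber lies along the axis the spheroid has stretched into
        theta = (
            truth.core_elongation[1]
            if truth.core_elongation
            else rng_bf.uniform(0, np.pi)
        )
        length = 0.7 * min(shape)
        width = max(6.0, 1.5 * sigma_px)
        fiber = (theta, length, width)
    debris = None
    if "debris" in truth.artifact_flags:
        # a compact clump, large enough for the count rule and placed clear
        # of the spheroid (a fixed number of rejection draws keeps the
        # random stream deterministic)
        if truth.core_centroid is not None:
            core_radius = np.sqrt(truth.core_area / np.pi) / params.pixel_size
            dradius = rng_bf.uniform(0.65, 0.9) * core_radius
        else:
            core_radius = 0.0
            dradius = rng_bf.uniform(0.05, 0.08) * min(shape)
        positions = rng_bf.uniform(0.12, 0.88, size=(12, 2)) * np.array(shape)
        drow, dcol = positions[0]
        for row, col in positions:
            if truth.core_centroid is None or np.hypot(
                row - truth.core_centroid[0], col - truth.core_centroid[1]
            ) > core_radius + dradius + 25:
                drow, dcol = row, col
                break
        debris = (float(drow), float(dcol), float(dradius))

    stacks: dict[str, ImageStack] = {}
    for role in ("brightfield", "hoechst", "pi"):
        if role not in channels:
            continue
        stack = np.empty((n_slices,) + tuple(shape), dtype=np.float32)
        for z in range(n_slices):
            if role == "brightfield":
                canvas = np.full(shape, params.bf_background, dtype=np.float32)
                bf_delta = params.bf_core_level - params.bf_background
                if truth.core_centroid is not None:
                    _render_core(
                        canvas, params, truth.core_centroid, truth.core_area,
                        bf_delta, mid, z, speckle, truth.core_elongation,
                    )
                if truth.second_core is not None:
                    r2, c2, a2 = truth.second_core
                    _render_core(
                        canvas, params, (r2, c2), a2, bf_delta, mid, z, None,
                    )
                for i, cell in enumerate(truth.cell_records):
                    dz = abs(z - int(cell_focal[i]))
                    if dz > 2:
                        continue
                    amp_f, width_f = _defocus(dz)
                    _add_blob(
                        canvas, cell.row, cell.col, sigma_px * width_f,
                        params.bf_cell_depth * amp_f, sign=-1.0,
                    )
                if chains and z == mid:
                    for angle, length_um in chains:
                        _render_chain(
                            canvas, truth.core_centroid, truth.core_area,
                            angle, length_um, params, 0.75 * sigma_px,
                            0.8 * params.bf_cell_depth,
                        )
                if fiber is not None:
                    _render_fiber(canvas, truth.core_centroid, fiber, depth=0.45)
                if debris is not None:
                    drow, dcol, dradius = debris
                    amp_f, width_f = _defocus(abs(z - mid))
                    alpha = _radial_alpha(
                        canvas.shape, (drow, dcol), dradius, 1.5 * width_f
                    )
                    canvas -= 0.4 * amp_f * alpha
            else:
                canvas = np.zeros(shape, dtype=np.float32)
                if role == "hoechst" and truth.core_centroid is not None:
                    _render_core(
                        canvas, params, truth.core_centroid, truth.core_area,
                        params.fluor_core_level, mid, z, None,
                        truth.core_elongation,
                    )
                    if truth.second_core is not None:
                        r2, c2, a2 = truth.second_core
                        _render_core(
                            canvas, params, (r2, c2), a2,
                            params.fluor_core_level, mid, z, None,
                        )
                amps = cell_amp_h if role == "hoechst" else cell_amp_p
                # the stained nucleus is smaller than the brightfield cell
                # body; PI fills the whole compromised nucleus brightly
                sigma_nuc = (0.65 if role == "hoechst" else 0.8) * sigma_px
                for i, cell in enumerate(truth.cell_records):
                    if role == "pi" and cell.alive:
                        continue
                    dz = abs(z - int(cell_focal[i]))
                    if dz > 2:
                        continue
                    amp_f, width_f = _defocus(dz)
                    _add_blob(
                        canvas, cell.row, cell.col, sigma_nuc * width_f,
                        amps[i] * amp_f,
                    )
            stack[z] = canvas
        if params.noise_sd > 0:
            noise_rng = np.random.default_rng(noise_children[role])
            stack += params.noise_sd * noise_rng.standard_normal(
                stack.shape, dtype=np.float32
            )
        np.clip(stack, 0.0, 1.0, out=stack)
        stacks[role] = ImageStack(stack, role, params.pixel_size, params.z_interval)
    return stacks, truth


def _render_chain(canvas, center, core_area_um2, angle, length_um, params,
                  sigma_chain, depth):
    """Radial strand of overlapping blobs rooted at the core boundary."""
    radius_px = np.sqrt(core_area_um2 / np.pi) / params.pixel_size
    length_px = length_um / params.pixel_size
    if length_px < 2.0 * sigma_chain:
        return  # no discernible strand when nothing has migrated
    u = (np.sin(angle), np.cos(angle))
    step = 1.0 * sigma_chain
    for t in np.arange(radius_px - 2.0, radius_px + length_px, step):
        _add_blob(
            canvas, center[0] + t * u[0], center[1] + t * u[1],
            sigma_chain, depth, sign=-1.0,
        )


def _render_fiber(canvas, center, fiber, depth):
    """Dark line through the spheroid core (lint-like artifact)."""
    theta, length, width = fiber
    t = np.linspace(-length / 2, length / 2, int(length * 2))
    rows = center[0] + t * np.sin(theta)
    cols = center[1] + t * np.cos(theta)
    ok = (
        (rows >= 0) & (rows < canvas.shape[0]) & (cols >= 0) & (cols < canvas.shape[1])
    )
    for r, c in zip(rows[ok][::2], cols[ok][::2]):
        _add_blob(canvas, r, c, width, depth, sign=-1.0)


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------


def well_seed_sequence(
    master_seed: int, well_index: int
) -> np.random.SeedSequence:
    """Counter-based per-well seed: child ``(well_index,)`` of the master seed.

    Wells are indexed by their sorted position in the layout, so the same
    master seed always reproduces the same plate, well by well.
    """
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(well_index,))


def generate_plate(
    layout: PlateLayout,
    params: SynthParams,
    seed: int,
    channels: Sequence[str] = ("brightfield", "hoechst", "pi"),
) -> tuple[dict[str, dict[str, ImageStack]], dict[str, WellTruth]]:
    """Render every well of a plate; layout-empty wells render no spheroid."""
    wells = sorted(layout.entries)
    if len(wells) != len(set(wells)):
        raise LayoutError("duplicate well ids in layout")
    stacks_by_well: dict[str, dict[str, ImageStack]] = {}
    truth_by_well: dict[str, WellTruth] = {}
    for index, well in enumerate(wells):
        entry = layout.entries[well]
        well_params = params
        if entry.role == "empty":
            well_params = replace(
                params,
                artifact_probabilities={**params.artifact_probabilities, "empty_well": 1.0},
            )
        stacks, truth = generate_well(
            well_params, well_seed_sequence(seed, index), channels=channels
        )
        stacks_by_well[well] = stacks
        truth_by_well[well] = truth
    return stacks_by_well, truth_by_well


def write_plate(
    directory: str | Path,
    stacks_by_well: Mapping[str, Mapping[str, ImageStack]],
    truth_by_well: Mapping[str, WellTruth],
    params: SynthParams | None = None,
) -> None:
    """Persist a generated plate: TIFFs per well/channel plus truth CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    well_rows = []
    cell_rows = []
    for well, stacks in stacks_by_well.items():
        save_well(stacks, directory, well_id=well)
        truth = truth_by_well[well]
        well_rows.append(
            {
                "well": well,
                "core_area_um2": truth.core_area,
                "core_row_px": truth.core_centroid[0] if truth.core_centroid else "",
                "core_col_px": truth.core_centroid[1] if truth.core_centroid else "",
                "n_spheroids": truth.n_spheroids,
                "n_cells": truth.n_cells,
                "n_dead": truth.n_dead,
                "artifacts": ";".join(sorted(truth.artifact_flags)),
                "planted_fold": truth.planted_fold,
            }
        )
        cf = truth_by_well[well].cells_frame()
        cf.insert(0, "well", well)
        cell_rows.append(cf)
    pd.DataFrame(well_rows).to_csv(directory / "truth_wells.csv", index=False)
    if cell_rows:
        pd.concat(cell_rows, ignore_index=True).to_csv(
            directory / "truth_cells.csv", index=False
        )
    if params is not None:
        params.to_yaml(directory / "synth_params.yaml")


# ---------------------------------------------------------------------------
# numbers-only screen tables
# ---------------------------------------------------------------------------


@dataclass
class ScreenSpec:
    """Configuration of a simulated primary screen (no images).

    Defaults mirror the validated screen's conditions: 1,012 compounds in
    triplicate at 10 μM against DMSO controls, 16 control wells per
    96-well plate, and well-level control noise of SD 0.08 on the
    normalized (fold) scale.  ``planted_high`` / ``planted_low`` /
    ``planted_toxic`` assign fold effects (and, for toxic, dead fractions)
    to disjoint compounds; everything else sits at fold 1.
    """

    n_compounds: int = 1012
    replicates: int = 3
    n_control_wells: int = 16
    control_noise_sd: float = 0.08
    planted_high: tuple[float, ...] = ()
    planted_low: tuple[float, ...] = ()
    planted_toxic: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    concentration_um: float = 10.0
    control_base_area: float = 40000.0
    baseline_dead: float = 0.05
    toxic_like_dead_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if not 2 <= self.n_control_wells <= 95:
            raise ConfigurationError("n_control_wells must be in [2, 95]")
        if self.control_noise_sd < 0:
            raise ConfigurationError("control_noise_sd must be >= 0")
        n_planted = (
            len(self.planted_high) + len(self.planted_low) + len(self.planted_toxic)
        )
        if n_planted > self.n_compounds:
            raise ConfigurationError("more planted effects than compounds")
        folds = list(self.planted_high) + list(self.planted_low) + [
            f for f, _ in self.planted_toxic
        ]
        if any(f <= 0 for f in folds):
            raise ConfigurationError("planted folds must be > 0")


def validation_screen_spec(
    seed: int,
    n_high: int = 24,
    high_range: tuple[float, float] = (1.7, 3.0),
    n_low: int = 36,
    low_range: tuple[float, float] = (0.17, 0.35),
    **overrides,
) -> ScreenSpec:
    """The primary-screen simulation: 24 high hits uniform in 1.7–3.0× and
    36 viable low hits uniform in 0.17–0.35×, planted among 1,012 compounds."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(7,)))
    high = tuple(np.round(rng.uniform(*high_range, size=n_high), 4))
    low = tuple(np.round(rng.uniform(*low_range, size=n_low), 4))
    return ScreenSpec(
        planted_high=high, planted_low=low, seed=int(seed), **overrides
    )


def generate_screen_table(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a numbers-only screen table plus per-compound truth labels.

    Returns ``(table, truth)``.  The table has one row per well with
    columns ``compound, concentration_um, replicate, plate, well,
    migration_area_um2, dead_fraction, role, excluded``; each replicate
    round fills its own set of plates, each plate holding
    ``96 - n_control_wells`` compounds plus the controls.  Truth has one
    row per compound with its planted fold, dead fraction and label in
    ``{high, low, toxic, none}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(spec.seed), spawn_key=(11,)))
    n = spec.n_compounds
    compounds = [f"C{i + 1:04d}" for i in range(n)]

    order = rng.permutation(n)
    fold = np.ones(n)
    dead = np.full(n, np.nan)
    label = np.array(["none"] * n, dtype=object)
    k = 0
    for f in spec.planted_high:
        fold[order[k]], label[order[k]] = f, "high"
        k += 1
    for f in spec.planted_low:
        fold[order[k]], label[order[k]] = f, "low"
        k += 1
    for f, df_tox in spec.planted_toxic:
        fold[order[k]], label[order[k]], dead[order[k]] = f, "toxic", df_tox
        k += 1

    per_plate = 96 - spec.n_control_wells
    rows = []
    for rep in range(1, spec.replicates + 1):
        for p0 in range(0, n, per_plate):
            chunk = list(range(p0, min(p0 + per_plate, n)))
            plate = f"R{rep}-P{p0 // per_plate + 1:02d}"
            well_ids = [f"{r}{c}" for c in range(1, 13) for r in "ABCDEFGH"]
            w = 0
            for _ in range(spec.n_control_wells):
                area = spec.control_base_area * rng.normal(1.0, spec.control_noise_sd)
                rows.append(
                    {
                        "compound": "DMSO",
                        "concentration_um": 0.0,
                        "replicate": rep,
                        "plate": plate,
                        "well": well_ids[w],
                        "migration_area_um2": max(area, 0.0),
                        "dead_fraction": float(
                            np.clip(rng.normal(spec.baseline_dead, 0.02), 0, 1)
                        ),
                        "role": "control",
                        "excluded": False,
                    }
                )
                w += 1
            for ci in chunk:
                area = (
                    spec.control_base_area
                    * fold[ci]
                    * rng.normal(1.0, spec.control_noise_sd)
                )
                if label[ci] == "toxic":
                    df_well = float(
                        np.clip(rng.normal(dead[ci], spec.toxic_like_dead_sd), 0, 1)
                    )
                else:
                    df_well = float(
                        np.clip(rng.normal(spec.baseline_dead, 0.02), 0, 1)
                    )
                rows.append(
                    {
                        "compound": compounds[ci],
                        "concentration_um": spec.concentration_um,
                        "replicate": rep,
                        "plate": plate,
                        "well": well_ids[w],
                        "migration_area_um2": max(area, 0.0),
                        "dead_fraction": df_well,
                        "role": "compound",
                        "excluded": False,
                    }
                )
                w += 1
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "compound": compounds,
            "planted_fold": fold,
            "planted_dead_fraction": dead,
            "label": label,
        }
    )
    return table, truth
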