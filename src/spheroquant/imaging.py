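"""Well image stacks, plate layouts and z-projections.

A well is imaged as a z-stack per channel (brightfield plus the vital dyes
Hoechst and propidium iodide).  Analysis never runs on raw stacks: the
collective-migration pipeline uses an extended-focus (all-in-focus)
composite of the brightfield stack, while fluorescence channels are
projected the same way before nuclei are segmented.  This module owns the
:class:`ImageStack` container, TIFF round-trip I/O, the plate-layout table
and the two projection operators.

Conventions: pixel coordinates are 0-based ``(row, col)`` with the origin
at the top-left; areas are reported in μm² via ``pixel_size**2``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml
from scipy.ndimage import uniform_filter

from .exceptions import ContractError, FormatError, LayoutError

CHANNEL_ROLES = ("brightfield", "hoechst", "pi")


@dataclass
class ImageStack:
    """A single-channel z-stack with physical calibration.

    Parameters
    ----------
    pixels
        3D array, ``(slice, row, col)``.
    channel_role
        One of ``brightfield``, ``hoechst``, ``pi``.
    pixel_size
        Lateral calibration, μm per pixel.
    z_interval
        Spacing between optical sections, μm.
    """

    pixels: np.ndarray
    channel_role: str
    pixel_size: float = 1.0
    z_interval: float = 25.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ContractError(
                f"stack must be 3D (slice, row, col); got shape {self.pixels.shape}"
            )
        if self.channel_role not in CHANNEL_ROLES:
            raise ContractError(f"unknown channel role {self.channel_role!r}")
        if not (self.pixel_size > 0 and self.z_interval > 0):
            raise ContractError("calibration must be strictly positive")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ContractError("stack intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


def zstack_depth(stack: ImageStack) -> float:
    """Total imaged depth in μm: ``(n_slices - 1) * z_interval``.

    Nine sections at 25 μm spacing span 200 μm.
    """
    return (stack.n_slices - 1) * stack.z_interval


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel maximum over slices (shape and dtype preserved)."""
    return stack.pixels.max(axis=0)


def extended_focus_projection(stack: ImageStack, window: int = 9) -> np.ndarray:
    """All-in-focus composite: per pixel, take the slice of maximal local variance.

    The focus measure is the intensity variance in a ``window``×``window``
    neighbourhood; every output pixel is copied verbatim from one input
    slice (no invented intensities).  Ties resolve to the lowest slice
    index, so a stack of identical slices projects to slice 0.
    """
    if window < 1:
        raise ContractError("window must be >= 1")
    px = stack.pixels
    if px.shape[0] == 1:
        return px[0].copy()
    x = px if px.dtype == np.float32 else px.astype(np.float64, copy=False)
    size = (1, window, window)
    local_mean = uniform_filter(x, size=size, mode="reflect")
    local_sq = uniform_filter(x * x, size=size, mode="reflect")
    focus = local_sq - local_mean * local_mean
    idx = np.argmax(focus, axis=0)
    return np.take_along_axis(px, idx[None, :, :], axis=0)[0]


def rescale_contrast(
    image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0
) -> np.ndarray:
    """Percentile contrast stretch to [0, 1] (float64).

    Degenerate images (no intensity spread between the percentiles) are
    returned as zeros rather than amplified noise.
    """
    lo, hi = np.percentile(image, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return np.clip((image.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def save_well(
    stacks: Mapping[str, ImageStack], directory: str | Path, well_id: str = "well"
) -> dict[str, Path]:
    """Write one multi-page TIFF per channel plus a YAML calibration sidecar.

    Returns the mapping channel role → written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta: dict[str, dict] = {}
    for role, stack in stacks.items():
        path = directory / f"{well_id}_{role}.tif"
        tifffile.imwrite(path, stack.pixels)
        paths[role] = path
        meta[role] = {
            "file": path.name,
            "pixel_size_um": float(stack.pixel_size),
            "z_interval_um": float(stack.z_interval),
        }
    with open(directory / f"{well_id}_channels.yaml", "w") as fh:
        yaml.safe_dump({"well": well_id, "channels": meta}, fh)
    return paths


def load_well(
    paths: Mapping[str, str | Path],
    pixel_size: float = 1.0,
    z_interval: float = 25.0,
) -> dict[str, ImageStack]:
    """Load per-channel TIFF stacks and attach calibration.

    ``paths`` maps channel role → TIFF file.  All channels must share the
    same row/col shape; 2D files are treated as single-slice stacks.
    """
    stacks: dict[str, ImageStack] = {}
    shape_2d: tuple[int, int] | None = None
    for role, path in paths.items():
        try:
            pixels = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        if pixels.ndim == 2:
            pixels = pixels[None, :, :]
        if pixels.ndim != 3:
            raise FormatError(f"{path}: expected 2D/3D TIFF, got ndim={pixels.ndim}")
        if shape_2d is None:
            shape_2d = pixels.shape[1:]
        elif pixels.shape[1:] != shape_2d:
            raise FormatError(
                f"channel {role!r} shape {pixels.shape[1:]} does not match {shape_2d}"
            )
        stacks[role] = ImageStack(pixels, role, pixel_size, z_interval)
    return stacks


def load_well_dir(directory: str | Path, well_id: str) -> dict[str, ImageStack]:
    """Load a well previously written by :func:`save_well` (sidecar-driven)."""
    directory = Path(directory)
    sidecar = directory / f"{well_id}_channels.yaml"
    if not sidecar.exists():
        raise FormatError(f"missing channel sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    stacks: dict[str, ImageStack] = {}
    for role, info in meta["channels"].items():
        loaded = load_well(
            {role: directory / info["file"]},
            pixel_size=info["pixel_size_um"],
            z_interval=info["z_interval_um"],
        )
        stacks[role] = loaded[role]
    return stacks


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

LAYOUT_ROLES = ("compound", "control", "empty")


@dataclass(frozen=True)
class WellEntry:
    compound: str | None
    concentration_um: float
    role: str


@dataclass
class PlateLayout:
    """Map well id → (compound, concentration, role).

    Control and empty wells carry no compound id; concentrations are
    non-negative μM.
    """

    entries: dict[str, WellEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well, e in self.entries.items():
            self._validate_entry(well, e)

    @staticmethod
    def _validate_entry(well: str, e: WellEntry) -> None:
        if e.role not in LAYOUT_ROLES:
            raise LayoutError(f"well {well}: unknown role {e.role!r}")
        if e.concentration_um < 0:
            raise LayoutError(f"well {well}: negative concentration")
        if e.role != "compound" and e.compound:
            raise LayoutError(f"well {well}: {e.role} wells carry no compound id")
        if e.role == "compound" and not e.compound:
            raise LayoutError(f"well {well}: compound wells need a compound id")

    def add(self, well: str, compound: str | None, concentration_um: float, role: str):
        if well in self.entries:
            raise LayoutError(f"duplicate well id {well!r}")
        e = WellEntry(compound, concentration_um, role)
        self._validate_entry(well, e)
        self.entries[well] = e

    @property
    def wells(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        layout = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                compound = row.get("compound") or None
                layout.add(
                    row["well"],
                    compound,
                    float(row.get("concentration_um") or 0.0),
                    row["role"],
                )
        return layout

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["well", "compound", "concentration_um", "role"])
            for well, e in self.entries.items():
                writer.writerow([well, e.compound or "", e.concentration_um, e.role])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        layout = cls()
        for well, spec in data["wells"].items():
            layout.add(
                well,
                spec.get("compound"),
                float(spec.get("concentration_um", 0.0)),
                spec["role"],
            )
        return layout


def default_screen_layout(
    compounds: list[str],
    n_control_wells: int = 16,
    concentration_um: float = 10.0,
) -> PlateLayout:
    """A 96-well layout: controls first (column-major), then compounds.

    Raises :class:`LayoutError` if controls plus compounds exceed 96 wells.
    """
    if n_control_wells + len(compounds) > 96:
        raise LayoutError("layout exceeds 96 wells")
    ids = [f"{r}{c}" for c in range(1, 13) for r in "ABCDEFGH"]
    layout = PlateLayout()
    for i in range(n_control_wells):
        layout.add(ids[i], None, 0.0, "control")
    for j, compound in enumerate(compounds):
        layout.add(ids[n_control_wells + j], compound, concentration_um, "compound")
    return layout
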