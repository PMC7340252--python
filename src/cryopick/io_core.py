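"""MRC and STAR input/output plus shared image primitives.

Conventions used throughout the package:

* images are 2-D ``float32`` arrays indexed ``[row, col]`` = ``[y, x]``;
* particle coordinates are 0-based pixel centers in the unbinned
  micrograph frame, ``x`` along columns and ``y`` along rows;
* STAR coordinate files use the Relion dialect
  (``_rlnCoordinateX``, ``_rlnCoordinateY``, optional
  ``_rlnAutopickFigureOfMerit`` for a pick score).

MRC files are read and written through :mod:`gemmi` (MRC2014/CCP4 map
container, modes 0/1/2); STAR files through :mod:`gemmi.cif`, of which
STAR is the underlying syntax.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Micrograph",
    "CoordinateSet",
    "ParticleStack",
    "FormatError",
    "read_micrograph",
    "write_micrograph",
    "read_coords",
    "write_coords",
    "read_class_metadata",
    "bin_image",
    "minmax_normalize",
    "standardize",
    "extract_particles",
    "extract_crop",
]

CROP_SIZE = 64  # every particle crop is resampled to this square size


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the expected dialect."""


@dataclass
class Micrograph:
    """A single motion-corrected cryo-EM image.

    Parameters
    ----------
    image:
        2-D intensity array, ``image[y, x]``.
    pixel_size:
        Physical pixel size in ångström per pixel, ``> 0``.
    id:
        Stable identifier, normally derived from the file name.
    """

    image: np.ndarray
    pixel_size: float
    id: str = "micrograph"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError(f"micrograph image must be 2-D, got {self.image.ndim}-D")
        if min(self.image.shape) < 64:
            raise ValueError(f"micrograph dimensions must be >= 64, got {self.image.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("micrograph contains non-finite pixels")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class CoordinateSet:
    """Particle centers on one micrograph, optionally with pick scores.

    Coordinates are 0-based pixel centers in the unbinned frame.
    ``score`` is ``None`` or an array of probabilities in ``[0, 1]``.
    """

    x: np.ndarray
    y: np.ndarray
    score: np.ndarray | None = None
    micrograph_id: str = "micrograph"

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=np.float64))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.score is not None:
            self.score = np.atleast_1d(np.asarray(self.score, dtype=np.float64))
            if self.score.shape != self.x.shape:
                raise ValueError("score must have the same length as x/y")
            if len(self.score) and (self.score.min() < 0 or self.score.max() > 1):
                raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)

    def __iter__(self):
        for i in range(len(self)):
            s = None if self.score is None else self.score[i]
            yield self.x[i], self.y[i], s

    @classmethod
    def empty(cls, micrograph_id: str = "micrograph") -> "CoordinateSet":
        return cls(np.empty(0), np.empty(0), None, micrograph_id)

    def subset(self, indices) -> "CoordinateSet":
        indices = np.asarray(indices)
        score = None if self.score is None else self.score[indices]
        return CoordinateSet(self.x[indices], self.y[indices], score, self.micrograph_id)


@dataclass
class ParticleStack:
    """Extracted, binned, 64x64-resampled and standardized particle crops.

    ``source`` keeps one ``(micrograph_id, x, y)`` record per crop so each
    crop can be traced back to its unbinned micrograph coordinate.
    """

    crops: np.ndarray
    source: list = field(default_factory=list)
    bin_factor: int = 1
    effective_pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.crops = np.asarray(self.crops, dtype=np.float32)
        if self.crops.size == 0:
            self.crops = self.crops.reshape(0, CROP_SIZE, CROP_SIZE)
        if self.crops.ndim != 3 or self.crops.shape[1:] != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crops must be N x {CROP_SIZE} x {CROP_SIZE}, got {self.crops.shape}")
        if len(self.source) != len(self.crops):
            raise ValueError("source records must match crop count")

    def __len__(self) -> int:
        return len(self.crops)

    def subset(self, indices) -> "ParticleStack":
        indices = np.asarray(indices)
        return ParticleStack(
            self.crops[indices],
            [self.source[int(i)] for i in indices],
            self.bin_factor,
            self.effective_pixel_size,
        )


# ---------------------------------------------------------------------------
# MRC


def read_micrograph(path, default_pixel_size: float = 1.0) -> Micrograph:
    """Read a single 2-D micrograph from an MRC2014 file (mode 0/1/2).

    A 3-D map is accepted only when it holds a single section.  A zero
    voxel size in the header falls back to ``default_pixel_size`` with a
    warning.
    """
    path = os.fspath(path)
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC file {path!r}: {exc}") from exc
    grid = ccp4.grid
    arr = np.array(grid, copy=True)  # indexed [x, y, z]
    if arr.ndim != 3:
        raise FormatError(f"unexpected MRC data rank {arr.ndim} in {path!r}")
    if arr.shape[2] != 1:
        raise FormatError(
            f"{path!r} is a 3-D stack with {arr.shape[2]} sections; expected a single 2-D image"
        )
    image = arr[:, :, 0].T  # -> [y, x]
    pixel_size = grid.unit_cell.a / grid.nu if grid.nu else 0.0
    if not pixel_size > 0:
        warnings.warn(
            f"{path!r} has zero voxel size in its header; "
            f"falling back to {default_pixel_size} A/px",
            stacklevel=2,
        )
        pixel_size = default_pixel_size
    mic_id = os.path.splitext(os.path.basename(path))[0]
    return Micrograph(image=image, pixel_size=float(pixel_size), id=mic_id)


def write_micrograph(micrograph: Micrograph, path) -> None:
    """Write a micrograph as a mode-2 (float32) MRC2014 map."""
    image = np.ascontiguousarray(micrograph.image.T[:, :, None], dtype=np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(image)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ny, nx = micrograph.shape
    ps = micrograph.pixel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * ps, ny * ps, ps, 90.0, 90.0, 90.0)
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(os.fspath(path))


# ---------------------------------------------------------------------------
# STAR

_X_TAG = "_rlnCoordinateX"
_Y_TAG = "_rlnCoordinateY"
_SCORE_TAG = "_rlnAutopickFigureOfMerit"
_DIST_TAG = "_rlnClassDistribution"
_RES_TAG = "_rlnEstimatedResolution"


def _star_block(path) -> gemmi.cif.Block:
    try:
        doc = gemmi.cif.read_file(os.fspath(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse STAR file {path!r}: {exc}") from exc
    return doc.sole_block()


def _block_tags(block: gemmi.cif.Block) -> list[str]:
    tags = []
    for item in block:
        if item.loop is not None:
            tags.extend(item.loop.tags)
        elif item.pair is not None:
            tags.append(item.pair[0])
    return tags


def read_coords(path, micrograph_id: str | None = None, one_based: bool = False) -> CoordinateSet:
    """Read particle coordinates from a Relion-style STAR file.

    ``one_based=True`` subtracts 1 from stored coordinates on read (some
    conventions count pixels from 1); the package itself always works
    0-based.
    """
    block = _star_block(path)
    xs = list(block.find_loop(_X_TAG))
    ys = list(block.find_loop(_Y_TAG))
    if not block.find_loop(_X_TAG).get_loop() or not block.find_loop(_Y_TAG).get_loop():
        # columns truly missing (an empty loop still exposes its tags)
        tags = _block_tags(block)
        if _X_TAG not in tags or _Y_TAG not in tags:
            raise FormatError(
                f"{os.fspath(path)!r} lacks {_X_TAG}/{_Y_TAG}; available columns: {tags}"
            )
    x = np.array([float(v) for v in xs], dtype=np.float64)
    y = np.array([float(v) for v in ys], dtype=np.float64)
    if one_based:
        x = x - 1.0
        y = y - 1.0
    scores = list(block.find_loop(_SCORE_TAG))
    score = np.array([float(v) for v in scores], dtype=np.float64) if scores else None
    if micrograph_id is None:
        micrograph_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return CoordinateSet(x=x, y=y, score=score, micrograph_id=micrograph_id)


def write_coords(coords: CoordinateSet, path, one_based: bool = False) -> None:
    """Write a coordinate set as a Relion-style STAR file."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("")
    columns = ["CoordinateX", "CoordinateY"]
    if coords.score is not None:
        columns.append("AutopickFigureOfMerit")
    loop = block.init_loop("_rln", columns)
    offset = 1.0 if one_based else 0.0
    for x, y, s in coords:
        row = [f"{x + offset:.6f}", f"{y + offset:.6f}"]
        if coords.score is not None:
            row.append(f"{s:.6f}")
        loop.add_row(row)
    doc.write_file(os.fspath(path))


def read_class_metadata(path) -> list[tuple[int, float, float]]:
    """Read per-class (distribution, resolution) rows from a model STAR file.

    Returns ``(class_id, distribution, resolution_A)`` tuples in file
    order.  Distributions are returned on the fraction scale exactly as
    stored; converting to percent is the caller's decision.
    """
    block = _star_block(path)
    dists = list(block.find_loop(_DIST_TAG))
    tags = _block_tags(block)
    if _DIST_TAG not in tags:
        raise FormatError(f"{os.fspath(path)!r} lacks {_DIST_TAG}; available columns: {tags}")
    if _RES_TAG not in tags:
        raise FormatError(f"{os.fspath(path)!r} lacks {_RES_TAG}; available columns: {tags}")
    ress = list(block.find_loop(_RES_TAG))
    return [(i, float(d), float(r)) for i, (d, r) in enumerate(zip(dists, ress))]


# ---------------------------------------------------------------------------
# image primitives


def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by an integer factor using block means.

    Trailing rows/columns that do not fill a complete ``factor x factor``
    block are dropped.
    """
    image = np.asarray(image)
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    if factor == 1:
        return image
    h, w = image.shape
    if factor > h or factor > w:
        raise ValueError(f"bin factor {factor} exceeds image dimensions {image.shape}")
    h2, w2 = h // factor, w // factor
    trimmed = image[: h2 * factor, : w2 * factor]
    return trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Affinely map an image to [0, 1]; a constant image maps to zeros."""
    image = np.asarray(image, dtype=np.float32)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def standardize(crop: np.ndarray) -> np.ndarray:
    """Standardize to zero mean / unit variance; flat crops map to zeros."""
    crop = np.asarray(crop, dtype=np.float32)
    sd = float(crop.std())
    if sd == 0.0:
        return np.zeros_like(crop)
    return (crop - crop.mean()) / sd


def _resize_bilinear(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    # local import: skimage pulls in a noticeable import chain
    from skimage.transform import resize

    return resize(
        image.astype(np.float32),
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)


def extract_crop(image: np.ndarray, x: float, y: float, box_px: int, bin_factor: int) -> np.ndarray | None:
    """Extract one standardized 64x64 crop centered at ``(x, y)``.

    The ``box_px`` window (unbinned pixels) is cut out, block-binned by
    ``bin_factor``, bilinearly resampled to 64x64 and standardized.
    Returns ``None`` when the window would cross the micrograph edge.
    """
    h, w = image.shape
    half = box_px // 2
    r0 = int(round(y)) - half
    c0 = int(round(x)) - half
    if r0 < 0 or c0 < 0 or r0 + box_px > h or c0 + box_px > w:
        return None
    window = image[r0 : r0 + box_px, c0 : c0 + box_px]
    binned = bin_image(window, bin_factor)
    resized = _resize_bilinear(binned, (CROP_SIZE, CROP_SIZE))
    return standardize(resized)


def extract_particles(
    micrograph: Micrograph,
    coords: CoordinateSet,
    box_px: int,
    bin_factor: int = 1,
) -> tuple[ParticleStack, int]:
    """Extract particle crops at the given centers.

    Returns the stack and the number of coordinates dropped because their
    window crossed the micrograph edge.
    """
    box_px = int(box_px)
    bin_factor = int(bin_factor)
    if bin_factor < 1:
        raise ValueError("bin_factor must be >= 1")
    crops = []
    source = []
    dropped = 0
    for x, y, _ in coords:
        crop = extract_crop(micrograph.image, x, y, box_px, bin_factor)
        if crop is None:
            dropped += 1
            continue
        crops.append(crop)
        source.append((micrograph.id, float(x), float(y)))
    arr = np.stack(crops) if crops else np.empty((0, CROP_SIZE, CROP_SIZE), dtype=np.float32)
    # binned box -> 64 px resample changes sampling by (box/bin)/64
    eff_ps = micrograph.pixel_size * bin_factor * (box_px // bin_factor) / CROP_SIZE
    stack = ParticleStack(arr, source, bin_factor, float(eff_ps))
    return stack, dropped
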