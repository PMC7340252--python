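"""Synthetic micrograph generator with ground truth, and pick-evaluation metrics.

The generator emulates the situations a cryo-EM picker has to cope with:
many copies of a roughly round / ring / rod shaped particle at known
centers, bright irregular ice-like contaminants, and additive Gaussian
noise at a controllable signal-to-noise ratio.  Every scene is fully
deterministic given its seed and comes with its ground truth (particle
centers and contaminant masks), so detection, classification and the full
training loop can be evaluated without any real data.

SNR here means the particle's peak contrast divided by the noise standard
deviation (which is fixed at 1), i.e. ``snr=1`` stamps particles whose
brightest pixel sits one noise sigma above background -- roughly what a
well-defocused micrograph looks like, while low values emulate
low-defocus, low-contrast imaging.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .io_core import CoordinateSet, Micrograph, write_coords, write_micrograph

__all__ = [
    "SceneParams",
    "SceneTruth",
    "PickMetrics",
    "particle_template",
    "generate_micrograph",
    "generate_dataset",
    "load_dataset",
    "evaluate_picks",
]


@dataclass
class SceneParams:
    """Parameters of one synthetic micrograph."""

    size: int = 1024                 # square image side, px
    # 5 A/px with the default 60 px diameter gives a 300 A particle: the bench
    # keeps physical dimensions realistic while sampling ~5x coarser than
    # typical micrographs so that scenes stay small
    pixel_size_A: float = 5.0
    n_particles: int = 30
    template: str = "disk"           # disk | ring | rod
    diameter_px: int = 60            # particle diameter, unbinned px
    n_contaminants: int = 0
    contaminant_intensity: float = 3.0   # multiple of the particle amplitude
    snr: float = 1.0                 # particle peak contrast / noise sd
    polarity: str = "bright"         # bright | dark
    count_jitter: bool = False       # Poisson-vary particle count per scene
    allow_overlap: bool = False      # let particles sit inside contaminant regions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("scene size must be >= 64")
        if self.diameter_px < 8:
            raise ValueError("particle diameter must be >= 8 px")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")
        if self.template not in ("disk", "ring", "rod"):
            raise ValueError("template must be disk, ring or rod")


@dataclass
class SceneTruth:
    """Ground truth for a generated scene."""

    centers: CoordinateSet
    contaminant_mask: np.ndarray
    params: SceneParams


@dataclass
class PickMetrics:
    precision: float
    recall: float
    f1: float
    mean_center_error_px: float
    tolerance_px: float
    n_matched: int = 0
    n_picked: int = 0
    n_truth: int = 0


def particle_template(kind: str, diameter_px: int) -> np.ndarray:
    """A soft-edged unit-amplitude particle template.

    ``disk``: filled circle; ``ring``: annulus (hollow particle seen
    top-down); ``rod``: elongated capsule (filament segment).  Peak value
    is 1; background 0.
    """
    d = int(diameter_px)
    r = d / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    cy = cx = (d - 1) / 2.0
    rr = np.hypot(yy - cy, xx - cx)
    edge = max(1.0, 0.1 * d)  # soft edge width
    if kind == "disk":
        t = np.clip((r - rr) / edge, 0.0, 1.0)
    elif kind == "ring":
        band = np.abs(rr - 0.7 * r)
        t = np.clip((0.25 * r - band) / edge, 0.0, 1.0)
    elif kind == "rod":
        half_len = r
        half_wid = 0.25 * r
        dx = np.maximum(np.abs(xx - cx) - (half_len - half_wid), 0.0)
        dist = np.hypot(dx, yy - cy)
        t = np.clip((half_wid - dist) / edge, 0.0, 1.0)
    else:
        raise ValueError(f"unknown template {kind!r}")
    return t.astype(np.float32)


def _place_centers(
    rng: np.random.Generator,
    size: int,
    n: int,
    min_sep: float,
    margin: float,
    forbidden: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample n centers >= min_sep apart and >= margin from edges.

    ``forbidden`` is an optional boolean mask of excluded positions
    (e.g. contaminant regions grown by a particle radius).
    """
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    max_attempts = max(2000, 500 * n)
    while len(xs) < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, size - margin)
        if forbidden is not None and forbidden[int(y), int(x)]:
            continue
        if xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() < min_sep**2:
                continue
        xs.append(x)
        ys.append(y)
    if len(xs) < n:
        raise ValueError(
            f"could not place {n} particles with spacing {min_sep:.0f} px "
            f"in a {size} px scene; achievable: {len(xs)}"
        )
    return np.array(xs), np.array(ys)


def _stamp(image: np.ndarray, tmpl: np.ndarray, x: float, y: float, amplitude: float) -> None:
    """Additively stamp a template with its center at (x, y), clipped at edges."""
    th, tw = tmpl.shape
    r0 = int(round(y)) - th // 2
    c0 = int(round(x)) - tw // 2
    h, w = image.shape
    tr0, tc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1 = min(h, r0 + th - tr0)
    c1 = min(w, c0 + tw - tc0)
    if r1 <= r0 or c1 <= c0:
        return
    image[r0:r1, c0:c1] += amplitude * tmpl[tr0 : tr0 + (r1 - r0), tc0 : tc0 + (c1 - c0)]


def _contaminant_blob(rng: np.random.Generator, size: int, diameter_px: int) -> np.ndarray:
    """An irregular ice-like region: the union of a few random ellipses."""
    mask = np.zeros((size, size), dtype=bool)
    scale = rng.uniform(1.0, 2.5) * diameter_px
    cx = rng.uniform(0.15 * size, 0.85 * size)
    cy = rng.uniform(0.15 * size, 0.85 * size)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(3, 6)):
        ex = cx + rng.uniform(-0.5, 0.5) * scale
        ey = cy + rng.uniform(-0.5, 0.5) * scale
        a = rng.uniform(0.3, 0.8) * scale
        b = rng.uniform(0.3, 0.8) * scale
        theta = rng.uniform(0, np.pi)
        dx = xx - ex
        dy = yy - ey
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def generate_micrograph(params: SceneParams) -> tuple[Micrograph, SceneTruth]:
    """Generate one synthetic micrograph and its ground truth.

    Background is Gaussian noise of unit standard deviation; each particle
    is the template stamped at a random rotation with peak amplitude
    ``snr`` (negated for dark polarity); contaminants are irregular blobs
    at ``contaminant_intensity`` times the particle amplitude.
    """
    rng = np.random.default_rng(params.seed)
    size = params.size
    sign = 1.0 if params.polarity == "bright" else -1.0
    amp = sign * params.snr

    n = params.n_particles
    if params.count_jitter and n > 0:
        n = max(1, int(rng.poisson(params.n_particles)))

    image = rng.standard_normal((size, size)).astype(np.float32)

    contaminant_mask = np.zeros((size, size), dtype=bool)
    for _ in range(params.n_contaminants):
        contaminant_mask |= _contaminant_blob(rng, size, params.diameter_px)
    image += (params.contaminant_intensity * amp) * contaminant_mask

    tmpl = particle_template(params.template, params.diameter_px)
    margin = params.diameter_px  # half a (2x diameter) box from the edge
    forbidden = None
    if contaminant_mask.any() and not params.allow_overlap:
        # keep particle centers a radius clear of any contaminant
        forbidden = ndimage.distance_transform_edt(~contaminant_mask) < params.diameter_px / 2.0
    if n > 0:
        xs, ys = _place_centers(
            rng, size, n, min_sep=float(params.diameter_px), margin=float(margin),
            forbidden=forbidden,
        )
        for x, y in zip(xs, ys):
            angle = rng.uniform(0.0, 360.0)
            rot = ndimage.rotate(tmpl, angle, reshape=False, order=1, mode="constant", cval=0.0)
            _stamp(image, rot, x, y, amp)
    else:
        xs, ys = np.empty(0), np.empty(0)

    mic = Micrograph(image=image, pixel_size=params.pixel_size_A, id=f"sim_{params.seed:06d}")
    truth = SceneTruth(
        centers=CoordinateSet(xs, ys, None, mic.id),
        contaminant_mask=contaminant_mask,
        params=params,
    )
    return mic, truth


def generate_dataset(
    n_micrographs: int,
    params: SceneParams,
    master_seed: int,
    out_dir: str | os.PathLike | None = None,
):
    """Generate a dataset of scenes with per-micrograph derived seeds.

    When ``out_dir`` is given, writes ``sim_*.mrc`` micrographs,
    ``sim_*_truth.star`` center files and a ``manifest.json`` from which
    the dataset can be regenerated bit-identically.
    """
    if n_micrographs < 1:
        raise ValueError("n_micrographs must be >= 1")
    seeds = [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n_micrographs) % (2**31)]
    scenes = []
    for i, s in enumerate(seeds):
        p = SceneParams(**{**asdict(params), "seed": s})
        mic, truth = generate_micrograph(p)
        mic.id = f"sim_{i:03d}"
        truth.centers.micrograph_id = mic.id
        scenes.append((mic, truth))
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        manifest = {"master_seed": master_seed, "n_micrographs": n_micrographs,
                    "params": asdict(params), "micrographs": []}
        for mic, truth in scenes:
            write_micrograph(mic, os.path.join(out_dir, f"{mic.id}.mrc"))
            write_coords(truth.centers, os.path.join(out_dir, f"{mic.id}_truth.star"))
            manifest["micrographs"].append(mic.id)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return scenes


def load_dataset(out_dir):
    """Regenerate a dataset from its manifest (no image files needed)."""
    with open(os.path.join(os.fspath(out_dir), "manifest.json")) as fh:
        manifest = json.load(fh)
    params = SceneParams(**manifest["params"])
    return generate_dataset(manifest["n_micrographs"], params, manifest["master_seed"])


def evaluate_picks(picked: CoordinateSet, truth: CoordinateSet, tolerance_px: float) -> PickMetrics:
    """Score picks against ground truth by greedy one-to-one center matching.

    Pick/truth pairs are matched in order of ascending center distance; a
    pair is accepted when both members are still unmatched and their
    distance is within ``tolerance_px``.  Precision = matched / picked,
    recall = matched / truth.
    """
    if tolerance_px <= 0:
        raise ValueError("tolerance must be > 0")
    n_p, n_t = len(picked), len(truth)
    if n_p == 0 or n_t == 0:
        return PickMetrics(0.0, 0.0, 0.0, 0.0, tolerance_px, 0, n_p, n_t)
    dx = picked.x[:, None] - truth.x[None, :]
    dy = picked.y[:, None] - truth.y[None, :]
    dist = np.hypot(dx, dy)
    pairs = np.argwhere(dist <= tolerance_px)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_p = np.zeros(n_p, dtype=bool)
    used_t = np.zeros(n_t, dtype=bool)
    errors = []
    for i, j in pairs[order]:
        if used_p[i] or used_t[j]:
            continue
        used_p[i] = True
        used_t[j] = True
        errors.append(dist[i, j])
    matched = len(errors)
    precision = matched / n_p
    recall = matched / n_t
    f1 = 0.0 if matched == 0 else 2 * precision * recall / (precision + recall)
    mean_err = float(np.mean(errors)) if errors else 0.0
    return PickMetrics(precision, recall, f1, mean_err, tolerance_px, matched, n_p, n_t)
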