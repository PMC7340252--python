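"""Reference-free 2D class averaging and %/Res-based class selection.

Particle quality is judged per 2D class by the ratio of its percentage
class distribution (percent of all particles landing in the class) to its
estimated resolution in ångström -- the %/Res score.  Well-populated,
well-resolved classes score high; sparsely populated or noisy classes
score near zero.  Classes with %/Res above a cutoff (0.1 by default) are
kept, and classification + selection is iterated until at least 90% of
the surviving particles are selected in a round.

The built-in classifier is a correlation-based hard-assignment k-means
over a grid of in-plane rotations and integer shifts.  It is not a
maximum-likelihood classifier of the kind production packages use; it
exists so the selection loop runs deterministically offline, and an
adapter (`classes_from_metadata`) accepts externally produced class
metadata (class distribution + estimated resolution) for production use.

Class resolution is estimated by Fourier ring correlation between
even/odd half-set averages, reported at the FRC = 0.5 crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import ParticleStack, standardize

__all__ = [
    "Class2D",
    "SelectionState",
    "num_classes",
    "classify2d",
    "frc_resolution",
    "select_classes",
    "classes_from_metadata",
    "iterate_selection",
]


@dataclass
class Class2D:
    """One 2D class: its average, members and quality statistics.

    ``resolution_A`` is ``None`` when the class could not be resolved
    (fewer than two members); its ratio is then defined as 0.
    """

    class_id: int
    distribution_pct: float
    resolution_A: float | None
    average: np.ndarray | None = None
    member_indices: np.ndarray | None = None

    @property
    def ratio(self) -> float:
        """%/Res: percentage distribution over resolution; 0 if unresolved."""
        if self.resolution_A is None or not self.resolution_A > 0:
            return 0.0
        return self.distribution_pct / self.resolution_A


@dataclass
class SelectionState:
    """Bookkeeping for one classification + selection round."""

    round: int
    n_input: int
    n_selected: int

    @property
    def selected_fraction(self) -> float:
        return self.n_selected / self.n_input if self.n_input else 0.0


def num_classes(n_particles: int) -> int:
    """Number of 2D classes for a given particle count: N/200, floor 2.

    Rounds half-up; small sets still get two classes so that selection
    remains meaningful.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    return max(2, int(np.floor(n_particles / 200.0 + 0.5)))


# ---------------------------------------------------------------------------
# classification


def _rotations(image: np.ndarray, angles: np.ndarray) -> np.ndarray:
    return np.stack(
        [ndimage.rotate(image, a, reshape=False, order=1, mode="constant", cval=0.0) for a in angles]
    )


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


def classify2d(
    stack: ParticleStack | np.ndarray,
    K: int,
    n_iter: int = 8,
    n_angles: int = 8,
    max_shift: int = 2,
    seed: int = 0,
) -> list[Class2D]:
    """Correlation k-means over a rotation/shift grid.

    Each round assigns every particle to the (class, rotation, shift)
    maximizing normalized cross-correlation, then recomputes class
    averages from the aligned members.  Deterministic given ``seed``.
    """
    crops = stack.crops if isinstance(stack, ParticleStack) else np.asarray(stack, dtype=np.float32)
    N, H, W = crops.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"cannot form {K} classes from {N} particles")
    eff_ps = stack.effective_pixel_size if isinstance(stack, ParticleStack) else 1.0

    rng = np.random.default_rng(seed)
    # seed each class from a single random particle: partition averages all
    # look alike (the mean washes noise out), which leaves nothing to break
    # the symmetry, whereas single-particle seeds let junk-dominated classes
    # emerge and drain junk away from the clean ones
    seeds = rng.choice(N, K, replace=False)
    averages = np.stack([standardize(crops[i]) for i in seeds])

    angles = np.arange(n_angles) * (360.0 / n_angles)
    shifts = [(dy, dx) for dy in range(-max_shift, max_shift + 1) for dx in range(-max_shift, max_shift + 1)]
    S = len(shifts)

    flat_particles = _unit_rows(crops.reshape(N, -1).astype(np.float32))
    assign = np.zeros(N, dtype=int)
    aligned = crops.copy()

    for _ in range(n_iter):
        # reference bank: class x angle x shift, rows unit-normalized
        bank = np.empty((K * n_angles * S, H * W), dtype=np.float32)
        row = 0
        for k in range(K):
            rots = _rotations(averages[k], angles)
            for a in range(n_angles):
                for dy, dx in shifts:
                    bank[row] = np.roll(rots[a], (dy, dx), axis=(0, 1)).ravel()
                    row += 1
        bank = _unit_rows(bank)
        corr = flat_particles @ bank.T  # (N, K*A*S)
        best = np.argmax(corr, axis=1)
        assign = best // (n_angles * S)
        rem = best % (n_angles * S)
        best_angle = angles[rem // S]
        best_shift = [shifts[r] for r in rem % S]

        # align members back into the class frame and re-average
        for i in range(N):
            dy, dx = best_shift[i]
            img = np.roll(crops[i], (-dy, -dx), axis=(0, 1))
            aligned[i] = ndimage.rotate(img, -best_angle[i], reshape=False, order=1, mode="constant", cval=0.0)
        for k in range(K):
            members = np.flatnonzero(assign == k)
            if len(members) == 0:
                # re-seed an empty class from the worst-matched particle
                worst = int(np.argmin(np.max(corr, axis=1)))
                assign[worst] = k
                members = np.array([worst])
            averages[k] = standardize(aligned[members].mean(axis=0))

    classes = []
    for k in range(K):
        members = np.flatnonzero(assign == k)
        pct = 100.0 * len(members) / N
        # resolution from the *unaligned* members: aligning junk against a
        # common reference imprints coherent structure on it (the
        # Einstein-from-noise effect) and would inflate junk resolutions
        res = frc_resolution(crops[members], eff_ps) if len(members) >= 2 else None
        classes.append(
            Class2D(
                class_id=k,
                distribution_pct=pct,
                resolution_A=res,
                average=averages[k].copy(),
                member_indices=members,
            )
        )
    return classes


def frc_resolution(members: np.ndarray, effective_pixel_size: float) -> float | None:
    """Resolution of a class by even/odd half-set Fourier ring correlation.

    Members are split even/odd into two half-averages; the FRC is
    computed per radial frequency shell and the resolution is 1/f at the
    first 0.5 crossing (linearly interpolated).  If the FRC never drops
    below 0.5 the Nyquist limit (2 x pixel size) is returned; with fewer
    than two members the class is unresolved (``None``).
    """
    members = np.asarray(members, dtype=np.float64)
    if len(members) < 2:
        return None
    half1 = members[0::2].mean(axis=0)
    half2 = members[1::2].mean(axis=0)
    n = members.shape[1]
    f1 = np.fft.fftshift(np.fft.fft2(half1))
    f2 = np.fft.fftshift(np.fft.fft2(half2))
    yy, xx = np.indices((n, n))
    c = n // 2
    radius = np.hypot(yy - c, xx - c).astype(int)
    nshell = n // 2
    num = np.zeros(nshell)
    den1 = np.zeros(nshell)
    den2 = np.zeros(nshell)
    cross = (f1 * np.conj(f2)).real
    p1 = np.abs(f1) ** 2
    p2 = np.abs(f2) ** 2
    for r in range(nshell):
        ring = radius == r
        num[r] = cross[ring].sum()
        den1[r] = p1[ring].sum()
        den2[r] = p2[ring].sum()
    den = np.sqrt(den1 * den2)
    frc = np.divide(num, den, out=np.zeros(nshell), where=den > 0)
    freqs = np.arange(nshell) / (n * effective_pixel_size)  # cycles / A
    for r in range(1, nshell):
        if frc[r] < 0.5:
            f_lo, f_hi = freqs[r - 1], freqs[r]
            v_lo, v_hi = frc[r - 1], frc[r]
            if v_lo == v_hi:
                f_cross = f_hi
            else:
                f_cross = f_lo + (v_lo - 0.5) / (v_lo - v_hi) * (f_hi - f_lo)
            if f_cross <= 0:
                f_cross = freqs[1] if nshell > 1 else 1.0 / (2 * effective_pixel_size)
            return float(1.0 / f_cross)
    return float(2.0 * effective_pixel_size)


# ---------------------------------------------------------------------------
# selection


def select_classes(
    classes: list[Class2D],
    cutoff: float = 0.1,
    round_index: int = 0,
) -> tuple[list[int], np.ndarray, SelectionState]:
    """Keep classes with %/Res strictly above the cutoff.

    Returns the selected class ids, the union of their member particle
    indices (empty when the classes carry no membership, e.g. external
    metadata), and the round's :class:`SelectionState`.
    """
    if not classes:
        raise ValueError("empty class list")
    selected_ids = [c.class_id for c in classes if c.ratio > cutoff]
    have_members = all(c.member_indices is not None for c in classes)
    if have_members:
        n_input = int(sum(len(c.member_indices) for c in classes))
        sel = [c.member_indices for c in classes if c.ratio > cutoff]
        indices = np.sort(np.concatenate(sel)) if sel else np.empty(0, dtype=int)
        n_selected = len(indices)
    else:
        total_pct = sum(c.distribution_pct for c in classes)
        sel_pct = sum(c.distribution_pct for c in classes if c.ratio > cutoff)
        indices = np.empty(0, dtype=int)
        n_input, n_selected = 1_000_000, int(round(1_000_000 * sel_pct / max(total_pct, 1e-12)))
    return selected_ids, indices, SelectionState(round_index, n_input, n_selected)


def classes_from_metadata(rows: list[tuple[int, float, float]]) -> list[Class2D]:
    """Build :class:`Class2D` records from (id, distribution, resolution) rows.

    Distributions are stored as fractions in class-averaging metadata
    files and are converted here to percent, the scale on which the
    %/Res cutoff of 0.1 discriminates.
    """
    return [
        Class2D(class_id=int(i), distribution_pct=100.0 * float(d), resolution_A=float(r))
        for i, d, r in rows
    ]


def iterate_selection(
    stack: ParticleStack | np.ndarray,
    cutoff: float = 0.1,
    stop_fraction: float = 0.90,
    max_rounds: int = 10,
    seed: int = 0,
    classify_kwargs: dict | None = None,
) -> tuple[np.ndarray, list[SelectionState]]:
    """Iterate classification + %/Res selection until 90% survive a round.

    Each round classifies the current subset into ``num_classes(n)``
    classes, keeps particles in classes with %/Res > cutoff, and stops
    once the kept fraction reaches ``stop_fraction``.  Returns indices
    into the original stack and the per-round states.
    """
    crops = stack.crops if isinstance(stack, ParticleStack) else np.asarray(stack, dtype=np.float32)
    eff_ps = stack.effective_pixel_size if isinstance(stack, ParticleStack) else 1.0
    kw = dict(classify_kwargs or {})
    current = np.arange(len(crops))
    states: list[SelectionState] = []
    for r in range(max_rounds):
        subset = crops[current]
        sub_stack = ParticleStack(subset, [("stack", 0.0, 0.0)] * len(subset), 1, eff_ps)
        K = num_classes(len(subset))
        classes = classify2d(sub_stack, K, seed=seed + r, **kw)
        _, sel_idx, state = select_classes(classes, cutoff, round_index=r)
        states.append(state)
        if len(sel_idx) == 0:
            raise RuntimeError(
                f"%/Res selection emptied the particle set in round {r}; "
                f"consider lowering the cutoff (currently {cutoff})"
            )
        current = current[sel_idx]
        if state.selected_fraction >= stop_fraction:
            return current, states
    warnings.warn(
        f"selection did not reach {stop_fraction:.0%} within {max_rounds} rounds; "
        "returning the last subset",
        stacklevel=2,
    )
    return current, states
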