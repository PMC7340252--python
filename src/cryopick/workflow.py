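"""Orchestration of the self-supervised picking workflow.

The loop trains a CNN picker without any external labels:

1. **Initialization** -- ab initio picks (or manual coordinates) on a
   small micrograph subset are filtered by iterative 2D classification,
   keeping particles in classes whose %/Res exceeds the cutoff until at
   least 90% of a round's particles survive.
2. **Iteration** -- train the CNN on the current particles (negatives
   resampled fresh from empty areas), pick the subset micrographs with
   it, classify the picks, and keep the qualified ones.  The iteration
   converges when at least 70% of the CNN's picks land in classes above
   the %/Res cutoff; after three iterations without convergence the last
   model is used anyway.
3. **Production picking** -- the final model picks every micrograph.

Every stage derives its seed from the master seed, so a run is
reproducible end to end; each iteration retrains from freshly
initialized weights rather than fine-tuning, which keeps runs
independent of iteration history.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import class2d, kpicker
from .io_core import (
    CoordinateSet,
    Micrograph,
    ParticleStack,
    extract_crop,
    read_micrograph,
    write_coords,
)
from .localpicker import LocalpickerParams, localpick

__all__ = [
    "WorkflowConfig",
    "WorkflowState",
    "initialize",
    "run_iteration",
    "check_convergence",
    "run_workflow",
    "production_pick",
]

logger = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    """All knobs of the workflow in one place.

    The defaults encode the published operating point: %/Res cutoff 0.1,
    90% selection stop for initialization, 70% qualified fraction for
    convergence, at most 3 training iterations, picking probability
    cutoff 0.9 and 30 training epochs.
    """

    particle_size: int = 240
    ratio_cutoff: float = 0.1
    init_stop_fraction: float = 0.90
    convergence_fraction: float = 0.70
    max_train_iterations: int = 3
    p_min: float = 0.9
    epochs: int = 30
    bin_factor: int = 4
    box_px: int | None = None          # extraction box; defaults to particle_size
    stride: int | None = None          # scan stride; defaults to particle_size // 4
    neg_per_pos: int = 1
    localpicker_bin: int = 9
    localpicker_threshold: float = 0.0015
    localpicker_auto_sigmas: float | None = None
    invert_contrast: bool = False
    classify_n_iter: int = 6
    classify_n_angles: int = 8
    classify_max_shift: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("init_stop_fraction", "convergence_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_train_iterations < 1:
            raise ValueError("max_train_iterations must be >= 1")

    def localpicker_params(self) -> LocalpickerParams:
        return LocalpickerParams(
            particle_size=self.particle_size,
            bin_size=self.localpicker_bin,
            threshold=self.localpicker_threshold,
            invert=self.invert_contrast,
            auto_threshold_sigmas=self.localpicker_auto_sigmas,
        )

    def stage_seed(self, stage: str, iteration: int = 0) -> int:
        """A reproducible per-stage seed derived from the master seed."""
        h = np.random.SeedSequence([self.seed, iteration, abs(hash(stage)) % (2**31)])
        return int(h.generate_state(1)[0] % (2**31))


@dataclass
class WorkflowState:
    """The iteration ledger of a workflow run."""

    iteration: int = 0
    model: "kpicker.KPickModel | None" = None
    coords: list[CoordinateSet] = field(default_factory=list)  # one per subset micrograph
    qualified_fraction: float = 0.0
    converged: bool = False
    ledger: list[dict] = field(default_factory=list)

    def n_particles(self) -> int:
        return sum(len(c) for c in self.coords)


def initialize(
    micrographs: list[Micrograph],
    config: WorkflowConfig,
    manual_coords: list[CoordinateSet] | None = None,
) -> WorkflowState:
    """Produce the initial class-filtered particle set.

    Uses the ab initio local-threshold picker unless manual coordinates
    are supplied, then runs the iterative %/Res selection.
    """
    if not micrographs:
        raise ValueError("at least one micrograph is required")
    if len(micrographs) > 40:
        warnings.warn(
            f"{len(micrographs)} micrographs in the training subset; "
            "20-40 are typical for the iterative stage",
            stacklevel=2,
        )
    if manual_coords is not None:
        coords = manual_coords
    else:
        params = config.localpicker_params()
        coords = [localpick(m, params) for m in micrographs]

    box = config.box_px or config.particle_size
    stacks = []
    owners = []  # (micrograph index, coordinate index)
    for mi, (mic, cs) in enumerate(zip(micrographs, coords)):
        for ci, (x, y, _) in enumerate(cs):
            crop = extract_crop(mic.image, x, y, box, config.bin_factor)
            if crop is not None:
                stacks.append(crop)
                owners.append((mi, ci))
    if len(stacks) < 10:
        raise RuntimeError(
            f"only {len(stacks)} extractable initial particles; at least 10 are required"
        )
    crops = np.stack(stacks)
    eff_ps = micrographs[0].pixel_size * config.bin_factor * (box // config.bin_factor) / 64.0
    stack = ParticleStack(crops, [(micrographs[o[0]].id, 0.0, 0.0) for o in owners], config.bin_factor, eff_ps)

    selected, states = class2d.iterate_selection(
        stack,
        cutoff=config.ratio_cutoff,
        stop_fraction=config.init_stop_fraction,
        seed=config.stage_seed("init-classify"),
        classify_kwargs=dict(
            n_iter=config.classify_n_iter,
            n_angles=config.classify_n_angles,
            max_shift=config.classify_max_shift,
        ),
    )
    n_surviving = len(selected)
    if n_surviving < 10:
        raise RuntimeError(f"only {n_surviving} particles survived initial selection")
    if n_surviving < 100:
        warnings.warn(
            f"only {n_surviving} particles survived initial selection; "
            "at least 100 are recommended for training",
            stacklevel=2,
        )
    # map survivors back to per-micrograph coordinate sets
    per_mic: dict[int, list[int]] = {}
    for s in selected:
        mi, ci = owners[s]
        per_mic.setdefault(mi, []).append(ci)
    out_coords = []
    for mi, cs in enumerate(coords):
        idx = per_mic.get(mi, [])
        out_coords.append(cs.subset(np.array(idx, dtype=int)) if idx else CoordinateSet.empty(cs.micrograph_id))
    state = WorkflowState(iteration=0, model=None, coords=out_coords)
    state.ledger.append(
        {
            "stage": "initialize",
            "n_initial_picks": sum(len(c) for c in coords),
            "n_selected": n_surviving,
            "selection_rounds": [
                {"round": s.round, "n_input": s.n_input, "n_selected": s.n_selected}
                for s in states
            ],
        }
    )
    return state


def run_iteration(
    state: WorkflowState,
    micrographs: list[Micrograph],
    config: WorkflowConfig,
) -> WorkflowState:
    """One train -> pick -> classify -> select cycle.

    Trains a freshly initialized CNN on the state's current particles,
    picks every subset micrograph, classifies the pooled picks and keeps
    the qualified ones as the next particle set.
    """
    iteration = state.iteration + 1
    seed = config.stage_seed("iteration", iteration)

    model_cfg = kpicker.PickModelConfig(epochs=config.epochs, seed=seed)
    model = kpicker.build_model(model_cfg)
    crops, labels = kpicker.make_training_set(
        micrographs,
        state.coords,
        particle_size=config.particle_size,
        box_px=config.box_px,
        bin_factor=config.bin_factor,
        neg_per_pos=config.neg_per_pos,
        seed=config.stage_seed("negatives", iteration),
    )
    model, history = kpicker.train_model(
        model, crops, labels, seed=config.stage_seed("train", iteration)
    )

    picks = [
        kpicker.kpick(
            model, mic, config.particle_size, p_min=config.p_min,
            stride=config.stride, bin_factor=config.bin_factor, box_px=config.box_px,
        )
        for mic in micrographs
    ]
    n_picked = sum(len(p) for p in picks)
    if n_picked == 0:
        raise RuntimeError(
            "the CNN picked no particles on the training subset; "
            f"consider lowering p_min (currently {config.p_min})"
        )

    box = config.box_px or config.particle_size
    crops_list, owners = [], []
    for mi, (mic, cs) in enumerate(zip(micrographs, picks)):
        for ci, (x, y, _) in enumerate(cs):
            crop = extract_crop(mic.image, x, y, box, config.bin_factor)
            if crop is not None:
                crops_list.append(crop)
                owners.append((mi, ci))
    eff_ps = micrographs[0].pixel_size * config.bin_factor * (box // config.bin_factor) / 64.0
    pick_stack = ParticleStack(
        np.stack(crops_list),
        [(micrographs[o[0]].id, 0.0, 0.0) for o in owners],
        config.bin_factor,
        eff_ps,
    )
    K = class2d.num_classes(len(pick_stack))
    classes = class2d.classify2d(
        pick_stack, K,
        n_iter=config.classify_n_iter,
        n_angles=config.classify_n_angles,
        max_shift=config.classify_max_shift,
        seed=config.stage_seed("classify", iteration),
    )
    _, selected_idx, sel_state = class2d.select_classes(classes, config.ratio_cutoff)
    qualified_fraction = len(selected_idx) / len(pick_stack)

    per_mic: dict[int, list[int]] = {}
    for s in selected_idx:
        mi, ci = owners[s]
        per_mic.setdefault(mi, []).append(ci)
    new_coords = []
    for mi, cs in enumerate(picks):
        idx = per_mic.get(mi, [])
        new_coords.append(cs.subset(np.array(idx, dtype=int)) if idx else CoordinateSet.empty(cs.micrograph_id))

    new_state = WorkflowState(
        iteration=iteration,
        model=model,
        coords=new_coords,
        qualified_fraction=qualified_fraction,
        converged=qualified_fraction >= config.convergence_fraction,
        ledger=state.ledger + [
            {
                "stage": "iteration",
                "iteration": iteration,
                "seed": seed,
                "n_train_particles": int((labels == 1).sum()),
                "final_train_accuracy": history.train_accuracy[-1],
                "final_val_accuracy": history.val_accuracy[-1],
                "n_picked": n_picked,
                "n_qualified": int(len(selected_idx)),
                "qualified_fraction": qualified_fraction,
            }
        ],
    )
    return new_state


def check_convergence(state: WorkflowState, config: WorkflowConfig) -> str:
    """Decide ``converged``, ``continue`` or ``cap_reached``.

    Converged when the qualified fraction reaches the convergence cutoff;
    capped when the iteration budget is exhausted first (the last model
    is still used for production picking).
    """
    if state.iteration < 1:
        raise ValueError("no completed iteration to judge")
    if state.qualified_fraction >= config.convergence_fraction:
        return "converged"
    if state.iteration >= config.max_train_iterations:
        return "cap_reached"
    return "continue"


def run_workflow(
    micrographs: list[Micrograph],
    config: WorkflowConfig,
    manual_coords: list[CoordinateSet] | None = None,
) -> WorkflowState:
    """Initialization plus training iterations until convergence or cap."""
    state = initialize(micrographs, config, manual_coords)
    while True:
        state = run_iteration(state, micrographs, config)
        decision = check_convergence(state, config)
        state.ledger.append({"stage": "convergence-check", "iteration": state.iteration, "decision": decision})
        if decision != "continue":
            return state


def production_pick(
    model: "kpicker.KPickModel",
    micrographs: list,
    config: WorkflowConfig,
    out_dir: str | os.PathLike | None = None,
    overwrite: bool = False,
) -> tuple[dict[str, CoordinateSet], dict]:
    """Pick every micrograph with the final model.

    ``micrographs`` may mix :class:`Micrograph` objects and MRC paths.
    With an output directory, one coordinate STAR file is written per
    micrograph and micrographs whose output already exists are skipped
    (resumable) unless ``overwrite`` is set.  Unreadable micrographs are
    logged and reported in the summary, not fatal.
    """
    results: dict[str, CoordinateSet] = {}
    summary = {"n_micrographs": len(micrographs), "n_picked_total": 0,
               "per_micrograph": {}, "skipped_existing": [], "failed": []}
    for item in micrographs:
        try:
            mic = item if isinstance(item, Micrograph) else read_micrograph(item)
        except Exception as exc:  # fault isolation: one bad file must not kill the run
            logger.warning("skipping unreadable micrograph %r: %s", item, exc)
            summary["failed"].append({"input": str(item), "error": str(exc)})
            continue
        out_path = None
        if out_dir is not None:
            os.makedirs(os.fspath(out_dir), exist_ok=True)
            out_path = os.path.join(os.fspath(out_dir), f"{mic.id}.star")
            if os.path.exists(out_path) and not overwrite:
                summary["skipped_existing"].append(mic.id)
                continue
        picks = kpicker.kpick(
            model, mic, config.particle_size, p_min=config.p_min,
            stride=config.stride, bin_factor=config.bin_factor, box_px=config.box_px,
        )
        results[mic.id] = picks
        summary["per_micrograph"][mic.id] = len(picks)
        summary["n_picked_total"] += len(picks)
        if out_path is not None:
            write_coords(picks, out_path)
    return results, summary
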