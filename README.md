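# cryopick

Self-supervised particle picking for single-particle cryo-EM.

Locating particles on micrographs is the first labor-intensive step of
single-particle analysis, and it is hard to automate: template matching
needs good templates, supervised CNN pickers need labeled data, and both
struggle with low-contrast micrographs and ice contamination.
`cryopick` closes the loop without any labels or pre-trained weights.
Starting from nothing but the particle diameter, it

1. proposes candidate particles with **Localpicker**, an ab initio
   local-threshold detector (bin → normalize → deviation-from-local-mean
   mask → connected components → minimum-distance cleanup);
2. filters them by reference-free **2D class averaging**, scoring each
   class by **%/Res** — percent class distribution divided by estimated
   resolution in Å — and keeping classes with %/Res > 0.1, iterated
   until ≥ 90 % of a round's particles survive;
3. trains a small **CNN** (three Conv3x3+MaxPool blocks, two dense
   layers, two-way softmax) on the filtered particles against crops from
   empty areas, picks with it at probability ≥ 0.9, and repeats
   pick → classify → select until ≥ 70 % of the CNN's picks are
   *qualified* (land in classes above the cutoff), capped at three
   iterations;
4. runs **production picking** over the full micrograph set, writing one
   Relion-style coordinate STAR file per micrograph.

Intensity-based picking cannot avoid bright crystalline ice — and does
not try to; the class filter keeps ice out of the training set, empty-
area negatives teach the CNN what ice looks like, and the trained picker
skips contaminated areas.

A synthetic-micrograph module (`cryopick.simdata`) generates scenes of
disk/ring/rod particles with known centers, ice-like contaminants and
controllable SNR, so the entire loop is testable without any data
download.  MRC (modes 0/1/2) and STAR I/O go through
[gemmi](https://gemmi.readthedocs.io).

## Worked example

Generate 20 contaminated micrographs, run the full loop, and score the
result against the generator's ground truth:

```python
import numpy as np
from cryopick import (SceneParams, generate_dataset, evaluate_picks,
                      WorkflowConfig, production_pick)
from cryopick.workflow import initialize, run_iteration, check_convergence

scenes = generate_dataset(
    20, SceneParams(size=1024, n_particles=40, diameter_px=60,
                    snr=1.0, n_contaminants=3), master_seed=0)
mics   = [m for m, _ in scenes]
truths = [t for _, t in scenes]

config = WorkflowConfig(particle_size=60, box_px=90, stride=20, epochs=10,
                        seed=0, localpicker_auto_sigmas=2.0)
state, decision = initialize(mics, config), "continue"
while decision == "continue":
    state = run_iteration(state, mics, config)
    decision = check_convergence(state, config)
    print(f"iteration {state.iteration}: qualified_fraction="
          f"{state.qualified_fraction:.2f} -> {decision}")

picks, summary = production_pick(state.model, mics, config)
recall = np.mean([evaluate_picks(picks[m.id], t.centers, 30.0).recall
                  for m, t in zip(mics, truths)])
print(f"production: {summary['n_picked_total']} picks, recall {recall:.2f}")
```

Output:

```
iteration 1: qualified_fraction=0.88 -> converged
production: 787 picks, recall 0.98
```

`qualified_fraction=0.88` means 88 % of the CNN's picks landed in 2D
classes with %/Res > 0.1 — above the 70 % convergence cutoff, so one
training iteration sufficed.  The 787 production picks recover 98 % of
the 800 true particles; on the same scenes the ab initio picker alone
puts ~6 % of its picks inside ice, the trained CNN under 1 %.

The same loop is scriptable from the shell:

```sh
cryopick simulate --n 20 --size 1024 --particles 40 --diameter 60 \
    --contaminants 3 --seed 0 --out data/
cryopick workflow --mrc-dir data/ --particle-size 60 --auto-threshold 2.0 \
    --stride 20 --seed 0 --out run/
cryopick evaluate --picks run/picks/sim_000.star \
    --truth data/sim_000_truth.star --tol 30
```

`localpick`, `train`, `pick` and `select` subcommands expose the
individual stages; `select` also accepts class metadata produced by an
external class-averaging program (`_rlnClassDistribution` /
`_rlnEstimatedResolution` columns).

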