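# contextcut4d

Simultaneous multi-phase graph-cut segmentation of lung tumors in 4D-CT.

A 4D-CT study is a set of k respiratory-phase CT volumes.  Contouring the
tumor in every phase is required for motion-aware radiotherapy planning
and is tedious by hand; per-phase automatic segmentation fails where an
edge is weak in one phase even though it is sharp in the neighbouring
phases.  `contextcut4d` segments **all phases at once from seeds drawn in
a single phase** by minimizing one global energy

    E_g(f) = Σ_i { R_i,v(f_v) + B_i,(v,w)(f_v, f_w) + C_i,(v,v')(f_v, f_v') }

over binary labels f_v ∈ {0, 1} (tumor / background) of every voxel of
every phase, where

* R_v(1) = −ln Pr(I_v|O), R_v(0) = −ln Pr(I_v|B) are regional costs from
  object/background histograms fitted to the user seeds (hard at seeds:
  R_v(0) = ∞ for object seeds, R_v(1) = ∞ for background seeds),
* B_(v,w) = λ₁ exp(−(I_v−I_w)²/2σ₁²) / dist(v,w) is the boundary cost of
  6-neighbors within a phase,
* C_(v,v') is a two-level Potts penalty on label disagreement between
  corresponding voxels of adjacent phases: 2λ₂σ₂ if |I_v−I_v'| ≤ τ, else
  λ₂σ₂.

All pairwise terms are submodular, so the exact global optimum is a
single max-flow/min-cut on a graph with one node per (phase, voxel),
intra-phase n-links and inter-phase context arcs.  Defaults: λ₁ = λ₂ = 1,
σ₁ = 0.5, σ₂ = 0.1, τ ≈ 0.0196 on window-normalized intensities.

The package ships the full pipeline: volume/seed I/O (NIfTI, MetaImage),
the energy model, the exact solver (with a brute-force oracle for
testing), DSC/ASSD evaluation, a synthetic 4-D phantom generator with
exact ground truth, and a CLI.

## Worked example

```python
from contextcut4d import (PhantomParams, generate_phantom, seeds_from_truth,
                          segment_4dct, evaluate_labeling)

truth = generate_phantom(PhantomParams(rng_seed=1))      # 6 phases, 48x64x64
seeds = seeds_from_truth(truth, phase_index=0, rng_seed=1)  # annotate phase 0 only
labeling = segment_4dct(truth.volume, seeds)             # one global min cut
report = evaluate_labeling(labeling, truth.masks, truth.volume.spacing)
for i, (d, a) in enumerate(zip(report.dsc_per_phase, report.assd_per_phase)):
    print(f"phase {i}: DSC {d:.3f}  ASSD {a:.2f} mm")
print(f"mean:    DSC {report.dsc_mean:.3f}  ASSD {report.assd_mean:.2f} mm")
```

prints

```
phase 0: DSC 0.978  ASSD 1.59 mm
phase 1: DSC 0.980  ASSD 1.40 mm
phase 2: DSC 0.975  ASSD 1.69 mm
phase 3: DSC 0.974  ASSD 1.87 mm
phase 4: DSC 0.977  ASSD 1.57 mm
phase 5: DSC 0.976  ASSD 1.66 mm
mean:    DSC 0.976  ASSD 1.63 mm
```

Seeds were drawn only in phase 0, yet every phase is segmented: DSC is
the volumetric overlap with the known phantom truth (1 = perfect), ASSD
the mean distance between the predicted and true tumor surfaces.  The
tumor moves 6 mm over the cycle, so phase 3 is 6 mm away from the
annotated phase.

The same pipeline from the shell:

```bash
contextcut4d simulate --out study/                 # phantom + truth + seeds
contextcut4d segment --manifest study/manifest.json --seeds study/seeds.json \
                     --mode context --out result/
contextcut4d evaluate --result result/ --truth study/ --out metrics/
contextcut4d sweep --out sweep/                    # parameter study on a phantom
```

`--mode no-context` forces λ₂ = 0 (independent per-phase cuts, the
baseline the context arcs are compared against) and `--mode single-phase`
segments only the annotated phase.

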