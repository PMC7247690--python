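# helicoil

Geometric descriptors for transmembrane signaling coiled coils.

Membrane-embedded sensor histidine kinases (the nitrate/nitrite sensor NarQ
of *E. coli* is the motivating system) relay a ligand-binding event in the
periplasmic sensor domain across the membrane through a four-helix bundle.
Three coupled degrees of freedom of that bundle carry the signal, and
`helicoil` measures all three on static dimer structures and on MD
trajectory windows:

* **helical rotation** — per-residue Crick angles φ<sub>C</sub>(i): the
  phase of Cα(i) about its local helix axis, measured in the plane normal
  to the local tangent, with zero pointing at the bundle axis.  A uniform
  shift Δφ<sub>C</sub> over a helix reads out rotation of that helix about
  its own axis;
* **diagonal scissoring** — cross-protomer distance profiles
  d(r) = |Cα(A, r) − Cα(B, r)| over the H1-side (residues 34–50) and
  H4-side (133–147) of the homodimer, whose opposing changes (H1–H1′
  closing while H4–H4′ opens) constitute the scissor mode;
* **piston shift** — the difference of the TM1 and TM2 Cα-centroid
  projections on the bundle axis z (the membrane normal),
  Δz = ⟨z⟩<sub>TM1</sub> − ⟨z⟩<sub>TM2</sub>.

Around these it provides the supporting analyses the problem needs: local
helix-axis fitting by the bisector construction, Kabsch CA superposition
and RMSD, backbone φ/ψ with an α-region classifier for the sensor–TM
linker (residues 34–38), α (i→i+4) versus 3₁₀-like (i→i+3) backbone
hydrogen-bond patterns, trailing-window trajectory analysis with
crystal-reference overlays and aligned snapshot export, and a two-state
structure comparison that quantifies how a break in the TM1–H1 linker
amplifies the piston shift.

Because the real system's trajectories are not shippable, the package
includes a first-class synthetic generator: ideal α-helices with exact
cylinder geometry, C2-symmetric four-helix dimers in which rotation,
scissoring, piston offsets and the linker break are imposed with known
magnitudes, and seeded two-state pseudo-trajectories with Gaussian
coordinate noise.  Every descriptor is validated by recovering those
imposed parameters.

## Worked example

Generate a ligand-bound-like → ligand-free-like switching trajectory,
analyse its trailing 200 ns, and compare the two end-state structures:

```python
import numpy as np
from helicoil import (AnalysisConfig, TwoStateTrajectorySpec, bound_like_spec,
                      free_like_spec, build_dimer, make_trajectory,
                      run_descriptors, window_last, compare_two_states)

spec = TwoStateTrajectorySpec(state_a=bound_like_spec(), state_b=free_like_spec(),
                              n_frames=101, frame_dt_ns=10.0,
                              noise_sigma_A=0.2, seed=42)
traj, labels = make_trajectory(spec)
result = run_descriptors(window_last(traj, 200.0), AnalysisConfig())
print("frames analysed:", len(result.frame_times))
print("contact A mean: %.2f A" % np.nanmean(result.contact['A'].values))
print("piston mean: %.2f A" % np.nanmean(result.piston.values))

bound, _ = build_dimer(bound_like_spec())
free, _ = build_dimer(free_like_spec())
cmp = compare_two_states(free, bound)
for k, v in cmp.summary.items():
    print(f"{k}: {v:.2f}")
```

prints

```
frames analysed: 20
contact A mean: 7.81 A
piston mean: -3.00 A
max_axial_TM1_vs_TM2_A: 2.86
mean_axial_TM1_vs_TM2_A: 2.79
max_axial_H1_vs_H4_A: 0.84
mean_axial_H1_vs_H4_A: 0.78
mean_crick_change_H1_deg: 25.74
core_superposition_rmsd_A: 0.95
```

Reading the numbers: the trailing window lies past the state switch, so
the residue 50–133 contact distance sits at its free-like value (7.8 Å,
vs 7.1 Å bound — the backbone proxy for the Arg50–Asp133 interaction)
and the piston series sits 3 Å from the bound-like level.  The two-state
comparison recovers the constructed mechanism: the TM1-vs-TM2 axial shift
(≈3 Å) is three times the H1-vs-H4 shift (≈1 Å) because the broken
TM1–H1 linker decouples the transmembrane helix, and the membrane-proximal
part of H1 is rotated by ≈26° about its own axis.

The same operations are scriptable from the shell:

```sh
helicoil simulate --preset two-state --n-frames 101 --noise 0.2 --seed 42 --out traj.pdb
helicoil analyze traj.pdb --dt-ns 10 --window-ns 200 --out results/
helicoil simulate --preset bound --out bound.pdb
helicoil simulate --preset free  --out free.pdb
helicoil compare free.pdb bound.pdb --out comparison.csv
helicoil snapshots traj.pdb --dt-ns 10 --out snapshots.pdb
```

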