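# freebeat

Beat-to-beat cardiac function from free-running 3D MRI.

Conventional cardiac cine MRI sorts data from many heartbeats into phase
bins, which assumes every beat is the same.  In arrhythmia — premature
ventricular contractions (PVCs) in particular — that assumption fails
exactly when the physiology is most interesting: individual ectopic beats
can eject far less blood than sinus beats, and averaging hides it.
`freebeat` implements joint reconstruction of **real-time 3D motion
fields** and a single **motion-corrected reference image** from a
continuously acquired, highly undersampled Cartesian acquisition, plus the
downstream beat-by-beat volumetry: propagate one ventricle segmentation
through the recovered motion, build a continuous volume curve, detect every
cardiac cycle, and report per-beat ejection fractions.  A deformable
digital two-ventricle phantom with closed-form ground truth supports
end-to-end validation.  It is written for researchers in dynamic MRI
reconstruction and quantitative cardiac imaging.

## Model

Per real-time frame `t` (20 consecutive readouts, ~48 ms) the acquired
k-space is modeled as

    s_t = S_t F C W(u_t) q + n,

where `q` is the static complex reference volume, `W(u_t)` backward
trilinear warping by the frame's displacement field, `C` coil-sensitivity
multiplication, `F` the orthonormal centered FFT and `S_t` the frame's
phase-encode sampling (an "L"-shaped golden-angle-rotated variable-density
leaflet).  The space-time displacement matrix is factored explicitly at low
rank,

    D = Phi Psi^T,   Phi ∈ R^{3N×R},  Psi ∈ R^{M×R},

and estimated by alternating minimization: conjugate-gradient solves for
`q`, adaptive mini-batch stochastic gradient descent with Sobolev
(smoothed-gradient) preconditioning for `(Phi, Psi)`, a per-frame
Gauss–Newton refinement of the temporal weights, and a zero-phase 4 Hz
Butterworth projection keeping `Psi` physiologically smooth.  Per-beat
ejection fraction is `EF = (EDV − ESV)/EDV × 100%` from the peaks and
subsequent troughs of the propagated-mask volume curve.

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Simulate the digital phantom (right-ventricle EF set analytically to
21.9%, beating at 60 cycles/min), reconstruct, and quantify — all from one
command:

```bash
freebeat pipeline --seed 1 --out-dir results/phantom_study
```

which prints, after about fifteen minutes of reconstruction on one CPU
core:

```
mean EF 22.2% +/- 0.3% over 13 cycles (ground truth 21.9%)
```

meaning: across the 13 cardiac cycles detected in the ~14-second
acquisition, the propagated segmentation's per-beat ejection fractions
averaged 22.2% with 0.3 points beat-to-beat spread, recovering the 21.9%
analytic ground truth of the phantom to well within a point — the same
validation logic used for the physical phantom experiment the simulator
mimics.  The output directory contains the reconstructed reference
(`reference.nii.gz` + JSON sidecar), the motion model (`motion.h5`), the
volume curve and per-cycle table (CSV), and an EF summary with a 1%-bin
histogram (`summary.json`).

The stages are also available individually (`freebeat simulate`,
`freebeat traj`, `freebeat recon`, `freebeat analyze`), and everything is
importable as a library:

```python
from freebeat.pipeline import run_phantom_study
result = run_phantom_study(seed=1)
print(result["mean_ef_pct"], result["std_ef_pct"], result["n_cycles"])
```

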