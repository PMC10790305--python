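# lamp — left-atrial modelling pipeline

`lamp` turns a pair of cardiac MR volumes — a contrast-enhanced angiogram
(CE-MRA, bright bloodpool) and a co-registered late-gadolinium-enhancement
scan (LGE-CMR, fibrosis contrast) — into a simulation-ready, labelled
left-atrial surface model, and quantifies how reproducible that model is
when different operators (or the same operator twice) supply the manual
inputs. It is written for cardiac-EP modelling groups who build
patient-specific atrial models and need to know how much of their
downstream simulation output is operator noise.

A processed case consists of:

1. **Labelled surface** — a triangle mesh of the atrial bloodpool with one
   structure label per element (body `LA`, appendage `LAA`, four pulmonary
   veins `LSPV/LIPV/RSPV/RIPV`), open at the four PVs and the mitral
   valve. Veins are identified from operator seed points by profiling the
   bloodpool cross-section radius r(s) along the seed → centre-of-mass
   line and taking the inflection (max of the second difference of the
   smoothed profile) as the vein–body junction. The mesh is refined to a
   target mean edge length, cleaned, and exportable to the openCARP
   `.pts/.elem/.lon` plain-text format in μm.
2. **Universal atrial coordinates (UAC)** — two discrete harmonic fields
   α, β ∈ [0,1] obtained by solving ∇²u = 0 with cotangent weights and
   Dirichlet boundaries built from four landmarks: α spans septal →
   lateral, β spans posterior mitral rim → roof → anterior mitral rim.
3. **Fibre field** — per-element unit tangent vectors transported from an
   atlas through UAC space (each fibre decomposed in the atlas element's
   local (∇α, ∇β) frame and reconstructed in the target frame); a
   deterministic rule-based field and a smooth stand-in field ship as the
   built-in atlas.
4. **Fibrosis map** — maximum LGE intensity projected ±3 mm along each
   element normal, thresholded by the image-intensity ratio
   (threshold = mean bloodpool intensity × factor; 0.97, 1.2, 1.32 by
   default), summarised as the fraction of body surface area at/above
   threshold (a score in [0,1]).
5. **Electrophysiology surrogate** — anisotropic eikonal activation from
   a stimulus at the RSPV rim with conductivities σl = 0.4, σt = 0.1 S/m
   (speed ∝ √σ, so a 2:1 anisotropy); conduction velocity CV = 1/‖∇LAT‖;
   and a two-variable excitable monodomain model (cubic activation,
   linear recovery) initiated from four Archimedean spirals in UAC space,
   with phase-singularity (rotor-core) detection by one-ring winding
   numbers, binned on a 101×101 UAC grid.

Paired models are compared with: per-structure Hausdorff/mean/median
surface distances, a two-way random-effects absolute-agreement
average-measures ICC for fibrosis scores, the fraction of matched elements
whose fibre directions agree within 22.5° (|a·b| ≥ cos π/8; 0° and 180°
both count), LAT Pearson correlation and total-activation-time difference
on the UAC grid, mean-CV difference, and Pearson + SSIM between PS maps.
All comparisons except the shape statistics use only correspondences
closer than 1 mm (the image resolution).

A synthetic-cohort generator provides fully self-contained test cases:
an ellipsoidal body with four vein tubes, an appendage and a mitral disc,
rendered into MRA/LGE-like volumes with a fibrotic wall patch of known
surface fraction, plus Gaussian "operator jitter" of every manual input.

## Worked example

`examples/05_operator_variability.py` processes one synthetic case twice —
truth inputs vs inter-operator jitter (σ = 3 mm on the mitral-valve
clipping sphere, the dominant shape-error source) — and compares the two
models end to end:

```
shape:   Hausdorff 9.90 mm, mean 0.175 mm, median 0.029 mm
fibres:  80.3% of matched elements within 22.5°
fibrosis scores A: {'0.97': 1.0, '1.2': 0.335, '1.32': 0.328}
fibrosis scores B: {'0.97': 1.0, '1.2': 0.335, '1.32': 0.329}
LAT:     r = 0.914, |ΔTAT| = 2.40 ms
CV:      mean difference +0.0053 m/s
PS maps: r = 0.151, SSIM = 0.842
```

Read: the surfaces agree to sub-voxel mean distance but the worst-case
(Hausdorff) error is ~10 mm, driven by mitral-valve placement; the planted
0.3-fraction fibrotic patch is recovered almost identically by both
"operators" at IIR 1.2/1.32 (at 0.97 the threshold falls below the
bloodpool mean, so the whole body scores); activation maps correlate at
r = 0.91 with a 2.4 ms total-activation-time difference; the mean CV
difference is ~5 mm/s; rotor-density maps agree moderately (SSIM 0.84).

The other examples build the surface model (`01`), compute UAC and compare
two different atlas fibre fields (`02` — they agree on only 36.9% of
elements, which calibrates how much fibre choice matters relative to
operator noise), map fibrosis (`03`), and run the pacing/AF surrogate
(`04`: total activation 152.5 ms from the RSPV rim, mean CV 0.49 m/s,
four spiral cores sustained at ≈4 rotors per frame).

## Command line

```
lamp run-case --config case.yaml        # volumes → mesh → UAC → fibrosis → EP
lamp compare-pair --a dirA --b dirB --out report.json
lamp make-cohort --n 10 --seed 1 --out cohort/
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. Every case
directory keeps a `time_log.json` of per-stage wall-clock seconds.

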