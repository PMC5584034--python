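# cbct4d — time-ordered 4D cone-beam CT reconstruction

Cone-beam CT on a radiotherapy linac rotates once around the patient in
about a minute.  Anything that moves *non-periodically* during that
minute — rectal gas, peristalsis, a drifting baseline — is smeared by a
conventional (FDK) reconstruction, and the usual respiratory 4D-CBCT
tricks do not apply because there is no periodic signal to bin by.

`cbct4d` implements the time-ordered alternative: the scan is split
into T consecutive time phases, each phase is reconstructed from a
narrow contiguous angular window by maximum-a-posteriori (MAP) Poisson
transmission tomography, and the missing angular information is
supplied by priors —

* **TVCS** — total-variation compressed sensing on a 200° window
  (180° + fan angle) per phase: `R = ||Psi mu||_1`;
* **PICCS** — prior-image constrained CS on a 90° window, with the
  TVCS phase image as static prior:
  `R = 0.1 ||Psi mu||_1 + 0.9 ||Psi(mu - mu_prior)||_1`;
* **TCGM** — a time-ordered chain-graph regularizer on a 90° window:
  `R = 0.1 ||Psi mu||_1 + 0.9 ||chain(mu_t; mu_{t-1}, mu_{t+1})||_1`,
  where the chain couples each phase to its temporal neighbors (doubled
  one-sided term at the chain ends) and all phases are reconstructed
  concurrently, so the constraint tracks the evolving neighbors.

The package contains everything needed to quantify the temporal
resolution of these methods on a digital phantom, end to end and with
no external data: an exact Siddon ray projector with its adjoint, FDK
filtered backprojection, a moving-sphere phantom simulator, phase
binning, the MAP solver, offset-detector projection extension, and the
penumbral-width / ROI-consistency metrics.

## Worked example

Reconstruct the moving-sphere phantom (3 cm air sphere translating
3 cm along the rotation axis during a 60 s scan) at the bundled
reduced-resolution preset and compare the four methods:

```python
from cbct4d import phantom_experiment, scaled_setup

setup = scaled_setup("3cm60s")
result = phantom_experiment(setup)
for method, width in result.widths_mm.items():
    print(f"{method:6s} {width:5.2f} mm")
print(f"TCGM narrows the TVCS penumbra by "
      f"{result.narrowing_percent('tcgm'):.1f}%")
```

prints (the exact values are what `scripts/acceptance.py` recomputes):

```
fdk    22.49 mm
tvcs   11.21 mm
piccs  10.47 mm
tcgm   10.49 mm
TCGM narrows the TVCS penumbra by 6.4%
```

The numbers are 10–90% penumbral widths of the air cavity's axial
profile in the middle phase (phase 5 of 9) — the experiment's surrogate
for temporal resolution.  The full-rotation FDK width approaches the
closed-form time-averaged occupancy width (0.8 x 30 mm = 24 mm);
narrowing the effective time window (200° -> 90°) roughly halves the
motion blur.  At this reduced resolution the two 90°-window refinements
land within a tenth of a millimetre of each other; see
`docs/methods.md` for what the temporal chain does and does not buy at
desk scale.

The same pipeline is scriptable from the shell:

```bash
cbct4d simulate --motion 3cm60s --out scan.h5
cbct4d fdk scan.h5 --out fdk.mha
cbct4d tvcs scan.h5 --init fdk.mha --window 200 --out-dir tvcs/
cbct4d evaluate tvcs/phase_05.mha
```

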