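# phaseq

Quantification of biomolecular condensates and integrin adhesion complexes
in fluorescence microscopy images.

Proteins of nascent cell–matrix adhesions (p130Cas, Nck, N-WASP, FAK,
paxillin, kindlin) undergo liquid–liquid phase separation in vitro and
cluster membrane-bound integrin on supported phospholipid bilayers.
Quantifying that behaviour from images requires a small set of careful
measurements, each of which this package implements as tested, reusable
code for anyone analysing condensate or adhesion images:

- **Partition coefficients (PC).** For each droplet segmented by a global
  Otsu threshold on a reference channel, PC = mean intensity inside the
  droplet / mean intensity of the surrounding bulk (outside the dilated
  droplet mask). Because the microscope PSF spreads interior intensity
  over the rim, small droplets measure dim; the PSF-calibrated correction
  multiplies the measured mean by `f(d) = plateau + (f0 − plateau)·e^(−k·d)`,
  a one-phase exponential association in the measured diameter `d`, fitted
  from discs of known intensity convolved with the measured PSF. Droplets
  with `d < 12 px` are discarded outright.
- **PSF calibration.** Per-channel FWHM from Gaussian fits to linescans
  through sub-resolution beads (focal plane = brightest z-plane per bead;
  FWHM = 2√(2 ln 2)·σ, averaged over beads).
- **FRAP kinetics.** Traces are background-subtracted, divided by a
  reference region to correct acquisition photobleaching, and normalized
  as `N(t) = (I(t) − I_post)/(I_pre − I_post)` so N(0) = 0 and the
  prebleach level is 1. Recovery is fit with `N = P(1 − e^(−kt))` or the
  biexponential `N = P(φ(1 − e^(−k₁t)) + (1 − φ)(1 − e^(−k₂t)))`; the two
  nested fits are compared with the extra sum-of-squares F test
  (`F = ((SS₁−SS₂)/(dof₁−dof₂))/(SS₂/dof₂)`), t½ = ln 2/k per component,
  immobile fraction = 1 − P. A bilayer-fluidity QC gate passes only if
  t½ < 10 s. Unresolved plateaus are flagged (reported as "nd").
- **TIRF cluster densities and enrichment.** Clusters per mm² of field
  area, and per-cluster fold enrichment over the unclustered membrane.
- **Adhesion morphometrics.** The printed ImageJ operator chain for
  counting nascent adhesions (rolling-ball background subtraction → CLAHE
  → exponential remap → contrast stretch → Laplacian-of-Gaussian →
  "Default dark" intermeans threshold → particle analysis, size 5–1000 px²),
  the fixed-threshold (5500–65535) total-adhesion-area measurement, an
  adhesion/cytoplasm partition coefficient, and GFP-expression gating
  (mean 1000–5000 a.u. after background subtraction).
- **Synthetic data.** Deterministic generators for every input class —
  bead stacks, droplet fields, FRAP traces, adhesion images, flat-field
  pairs — each with a ground-truth record, so the whole pipeline is
  testable without raw microscope data.

## Worked example

```python
import numpy as np
from phaseq import condensates, psf, synthetic
from phaseq.synthetic import DropletSpec

# a synthetic 2-channel droplet field: true PC 3.0 (647) and 1.5 (488)
bulk = {"647": 100.0, "488": 120.0}
specs = [DropletSpec((70.0 + 100*i, 70.0 + 100*j), 13.0 + 4*(3*i + j),
                     {"647": 300.0, "488": 180.0})
         for i in range(3) for j in range(3)]
images, truth = synthetic.make_droplet_image(
    specs, bulk, psf_fwhm=4.0, noise_sd=2.0, seed=7, shape=(340, 340))

curve = psf.build_correction_curve(psf.gaussian_psf(4.0))
labels = condensates.segment_droplets(images["647"])
bulk_est = {ch: condensates.bulk_mean(labels, images[ch], 5) for ch in images}
records = condensates.partition_coefficients(
    labels, images, bulk_est, curves={ch: curve for ch in images})
print(condensates.summarize_partition(records))
```

prints

```
  channel   pc_mean    pc_sem  n
0     647  3.152156  0.042722  9
1     488  1.642253  0.031565  9
```

i.e. the blur-corrected partition coefficients recover the generator's
truth (3.0 and 1.5) from nine droplets of 13–45 px diameter; `pc_sem` is
the standard error over droplets and `n` the number of non-discarded
droplets. (The residual few-percent overshoot is the bulk signal blurred
into the droplet mask — see `docs/methods.md`.)

A FRAP example:

```python
import math
from phaseq import frap
table, gt = synthetic.make_frap_series(
    (0.5, 0.4), (math.log(2)/2, math.log(2)/39), noise_sd=5.0, seed=3)
norm = frap.normalize_trace(frap.FrapTrace.from_dataframe(table))
fit1, fit2, sel, best = frap.fit_and_select(norm.t, norm.normalized)
print(sel.chosen, [round(t, 2) for t in best.t_half])
```

prints `double [1.96, 36.94]` — the F test picks the biexponential model
and recovers the simulated fast/slow half-times of 2 s and 39 s from a
single noisy trace.

## Command line

`phaseq` exposes `simulate`, `calibrate-psf`, `quantify-droplets`,
`cluster-density`, `fit-frap`, `count-adhesions`, and `total-area`
subcommands over the same library functions; all tunables live in one YAML
config (`--config`), outputs are CSV/JSON with a run manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates synthetic inputs from the given seed and runs the three main
pipelines end-to-end — PSF-corrected droplet partition coefficients
(3-channel field with shading and shot noise), biexponential FRAP fitting
with F-test model selection on averaged replicates, and the full
adhesion-counting chain plus adhesion partitioning — printing the
recovered quantities to stderr and writing the results JSON to `--out`.
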