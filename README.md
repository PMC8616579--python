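# synaptodetect

Rules-based detection, segmentation and longitudinal quantification of
fluorescently tagged synaptic puncta in volumetric two-photon microscopy,
plus the evaluation metrics (annotation agreement, two-channel overlap,
spine colocalization), population-level plasticity statistics, and FRAP
(fluorescence recovery after photobleaching) curve fitting that go with
such experiments.

The intended user images endogenously tagged AMPA-type glutamate receptors
(e.g. SEP-GluA1) in vivo: every excitatory synapse appears as a compact
bright punctum in an anisotropic image stack (typically 0.096 µm pixels in
XY, 1 µm z-steps, PSF FWHM ≈ 0.55/0.57/2.50 µm in X/Y/Z), and the job is
to find, delineate and measure hundreds of thousands of them without human
annotation.

## The detection rule system

A synapse is *defined* as an image feature satisfying a fixed set of rules
rather than by a trained model:

1. **Candidates** are per-plane local maxima of the stack blurred with a
   Gaussian kernel of σ = 5 × 5 × 1 px (x, y, z).
2. Candidates closer than 3 px in-plane are deduplicated by a greedy
   **farthest-first traversal**.
3. Dark regions (blood vessels, somata) with blurred z-score < −1 are
   excluded.
4. Each candidate is matched against a family of **elliptical templates**
   (areas 20–150 px, axis ratios 1–2.5, 12 orientations, rasterised inside
   a 65 × 65 window with a 3-px background ring) and scored by

   SNR = (mean foreground − mean background) / σ(window),

   keeping the template that maximises SNR.
5. A candidate is accepted only if **all five conditions** hold: template
   area in [20, 150] px; axis ratio in [1, 2.5]; SNR above the 90th
   percentile of 300 random null locations; SNR retained to ≥ 2/3 when the
   plane is averaged with its two neighbours (synapses span several planes,
   noise does not); and SNR not increased by widening the average to seven
   planes (artifacts span many more planes than synapses).
6. Accepted detections that overlap in XY on adjacent z-planes are merged
   into 3D synapses; only synapses spanning **2–6 consecutive planes** are
   kept (the axial PSF makes anything longer an unresolvable merge).

Longitudinal sessions are integer-translation aligned, detected
independently, normalised to the pooled-baseline mean intensity, and
compared to baseline with a two-sided Mann–Whitney U test. FRAP recovery is
fitted over 0–30 min with the one-phase decay

    Y(t) = (Y0 − Plateau) · exp(−k·t) + Plateau,

whose plateau (relative to the normalised pre-bleach level) is the mobile
receptor fraction and τ = 1/k the exchange time constant.

Because real annotated stacks are large and scarce, the package ships a
**synthetic ground-truth generator** that emulates the imaging physics
(elliptical puncta of 0.125–1.25 µm², Gaussian PSF, background, read and
shot noise, dark vessels, longitudinal sessions with optional
potentiation), so every stage is testable against known truth.

## Worked example

```bash
synaptodetect simulate --shape 20 256 256 --n 40 --seed 7 --out vol.tif --truth truth.csv
synaptodetect detect vol.tif --out-prefix run1 --seed 7
synaptodetect evaluate --a run1_labels.tif --b truth.csv --mode pr --out pr.json
```

prints

```
wrote vol.tif with 40 puncta
39 synapses (threshold 1.080); wrote run1_synapses.csv
{
  "precision": 1.0,
  "recall": 0.95,
  "f1": 0.9743589743589743
}
```

i.e. the detector found 39 synapses in a volume with 40 planted puncta
(null SNR threshold 1.08); every detection overlaps a true punctum by at
least half its voxels (precision 1.0) and 38 of the 40 planted puncta were
recovered (recall 0.95). The per-synapse table carries centroids, z-spans,
voxel counts, summed intensities and maximum single-plane areas:

```
id,centroid_z,centroid_y,centroid_x,z_span,n_voxels,total_intensity,max_plane_area_px
1,2.56,40.99,172.99,2,168,25327.8,89
2,3.05,42.95,219.03,3,355,56690.0,125
```

Fitting a simulated FRAP cohort (66 bleached spines, noise σ = 0.02) at
recovery parameters plateau = 0.526 and k = 0.09 /min:

```python
import numpy as np
from synaptodetect.synthetic import simulate_frap_trace
from synaptodetect.frap import fit_frap

t = np.array([0., 2., 5., 10., 15., 20., 25., 30.])
traces = [simulate_frap_trace(0.0, 0.526, 0.09, t, 0.02, seed=s)["value"] for s in range(66)]
print(fit_frap((t, np.mean(traces, axis=0))).summary())
```

```
One-phase decay fit  Y(t) = (Y0 - Plateau) exp(-k t) + Plateau
  Y0       = 0.0000
  Plateau  = 0.5296
  k        = 0.0885 /min
  tau      = 11.30 min
  SSE      = 1.686e-05  (n = 8)
```

A plateau of ~0.53 means about half the receptor pool is mobile and is
exchanged with a time constant of ~11 min.

## Layout

| module | contents |
| --- | --- |
| `synaptodetect.core` | domain types, coordinate conventions, `DetectionConfig` |
| `synaptodetect.io` | TIFF stacks, label volumes, detection tables, annotations |
| `synaptodetect.detect` | blur, per-plane maxima, farthest-first pruning, exclusion mask |
| `synaptodetect.templates` | ellipse rasterisation, template family, SNR scoring |
| `synaptodetect.pipeline` | five acceptance rules, null threshold, z-merge, full pipeline |
| `synaptodetect.evaluate` | agreement, precision/recall, channel overlap, colocalization |
| `synaptodetect.quantify` | per-synapse measures, baseline normalisation, Mann–Whitney, alignment |
| `synaptodetect.synthetic` | ground-truth volume generator, longitudinal sessions, FRAP traces |
| `synaptodetect.frap` | trace normalisation, one-phase decay fit, mobile fraction |
| `synaptodetect.cli` | `synaptodetect simulate / detect / evaluate / quantify / frap` |

Coordinate convention throughout: 0-based `(z, y, x)` indices, plane 0 is
the first TIFF page, physical position = index × voxel size (µm).
Intensities are never rescaled at I/O time.
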