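# flimcyte

Single-cell analysis of label-free optical metabolic imaging (OMI) for
tracking somatic-cell reprogramming.  Two-photon FLIM/TCSPC records a
photon-arrival histogram in every pixel for the two autofluorescent
metabolic coenzymes, NAD(P)H and FAD; as erythroid progenitor cells
(EPCs) reprogram through an intermediate stage (IM) into induced
pluripotent stem cells (iPSCs), their metabolism — and therefore their
autofluorescence — changes.  `flimcyte` turns those image cubes into
per-cell metabolic state, predicted reprogramming status, and a
pseudotime ordering, and ships a ground-truthed synthetic FLIM
generator so the whole chain is testable without microscope data.

The chain:

1. **synthetic** — render micropattern scenes of EPC/IM/iPSC cells with
   known per-cell decay parameters, Poisson photon noise, a 240 ps FWHM
   IRF, and dark nuclei.
2. **decayfit** — per-pixel fit of the IRF-convolved two-component decay
   `I(t) = A[α₁e^(−t/τ₁) + α₂e^(−t/τ₂)] + C` (α₁+α₂ = 1, τ₁ ≤ τ₂) with
   3×3 spatial binning and low-signal exclusion; mean lifetime
   τ_m = α₁τ₁ + α₂τ₂.
3. **segmentation** — dark-nucleus detection (smooth → threshold 0.3 →
   label → 15–500 px area filter), seeded geodesic propagation of cells,
   cytoplasm = cell ∖ nucleus.
4. **features** — 11 metabolic parameters per cytoplasm (I, α₁, τ₁, τ₂,
   τ_m per channel, plus the optical redox ratio
   I_NADPH/(I_NADPH+I_FAD)) and 8 nuclear morphometry parameters per
   nucleus; z-score tables and average-linkage ordering.
5. **classify** — random forest (and logistic / kNN / naive Bayes) under
   repeated 15-fold cross-validation, gain-ratio feature weights,
   one-vs-rest ROC/AUC, accuracy-vs-parameter-count curves.
6. **trajectory** — UMAP (weighted-Jaccard metric), Leiden clustering, a
   centroid-MST principal graph with pruned long edges, geodesic
   pseudotime from the EPC-rich root, and per-parameter Moran's I along
   the embedding.

See `docs/methods.md` for the model details and every default.

## Worked example

```python
import numpy as np
from flimcyte import (TimeAxis, IRFModel, DecayParams, FitConfig,
                      render_decay, fit_pixel)

axis = TimeAxis()                      # 512 bins over 12.5 ns
irf = IRFModel(fwhm=0.240)             # 240 ps FWHM Gaussian IRF
truth = DecayParams(alpha1=0.70, tau1=0.40, tau2=2.50, amplitude=20000)

hist = render_decay(truth, axis, irf, poisson=True, rng=1)
fit = fit_pixel(hist, axis, irf, FitConfig(peak_threshold=0))
p = fit.params
print(f"alpha1={p.alpha1:.3f} tau1={p.tau1:.3f} ns "
      f"tau2={p.tau2:.3f} ns tau_m={p.tau_m:.3f} ns")
```

prints

```
alpha1=0.706 tau1=0.392 ns tau2=2.500 ns tau_m=1.011 ns
```

i.e. from a single noisy 20 000-photon histogram the fit recovers the
short-component fraction within 0.006, both lifetimes within ~10 ps,
and a mean lifetime of 1.011 ns against the true
α₁τ₁+α₂τ₂ = 1.030 ns.

The same works at scene scale from the command line:

```sh
flimcyte run-all --config my_run.yaml --seed 7 --outdir out/
```

which writes the photon cubes (`scene.h5`), lifetime maps
(`lifetime_*.tif` + JSON sidecars), label masks, the per-cell feature
table (`cells_features.csv`, 11 metabolic + 8 nuclear columns), the
classifier report, trajectory columns, and a `manifest.json` with a
SHA-256 checksum of every artifact.  Rerunning with the same seed
reproduces the checksums.

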