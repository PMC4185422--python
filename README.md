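# vesiflux

Quantification machinery for asking how much of a cell's bulk endocytic
protein flux passes through clathrin-coated pits — re-implemented as a
tested, reusable Python library and exercised end-to-end on synthetic
confocal scenes with known ground truth.

## The scientific problem

In a pulse-label endocytosis experiment, all surface proteins are tagged
(e.g. with a reducible biotin label), cells internalise for a short time,
the remaining surface label is stripped (MESNa reduction), and the earliest
intracellular vesicles are imaged together with a clathrin-pathway cargo
marker (transferrin). The quantitative questions are:

- **Pixel level** — what share of the internalised-label intensity lies on
  cargo-marker-positive pixels, and how much of that overlap would occur by
  chance? The chance level is estimated by repeating the measurement with
  one channel translated ~500 nm out of register.
- **Object level** — for each detected 3D vesicle, what is its mean cargo
  intensity ("cargo load"), and is it above or below an empirical
  background cutoff? The background distribution is built by offsetting the
  cargo channel 20 voxels (~500 nm) along x and re-sampling the same
  objects; the 95th percentile of that distribution defines cargo-negative
  vesicles, so a fraction positive near 1 means essentially every vesicle
  carries the clathrin-pathway cargo. The cargo-load histogram of the
  positive population is summarised by a single Gaussian
  A·exp(−(x−μ)²/2σ²), consistent with stochastic cargo incorporation.
- **Calibration** — how completely does the stripping step remove surface
  label? A serial dilution of labelled into unlabelled lysate gives a
  log-log standard curve; the treated signal is inverted through it, or
  reported as a bound ("more than X% removed") when it falls below the
  lowest standard.
- **Proteome level** — plasma-membrane abundance
  PMA(x) = copies(x) / Σ copies(plasma-membrane proteins) × 100,
  and classification of SILAC heavy/light ratios of surface proteins
  against a band of mean ± 2 SD of the non-biotinylated internal-control
  distribution (log2 scale): above = accumulated at the surface when
  coated-pit uptake is blocked, below = depleted.

No imaging data accompany the original study, so the package ships a
synthetic-scene generator (`vesiflux.scenes`) producing multi-channel
confocal stacks with Gaussian vesicle spots, per-vesicle cargo loads drawn
from a single Gaussian (with a configurable cargo-negative subpopulation),
PSF blur, Poisson + read noise, residual plasma-membrane background and
rare large hollow macropinosomes — with full ground truth, so every
pipeline stage is validated by parameter recovery.

## Worked example

`examples/object_cargo_classification.py` generates a scene in which 90%
of 800 vesicles carry cargo, then runs the full object pipeline:

```
detected 610 objects from 800 true vesicles
null cutoff (95th percentile of offset background): 23.88
cargo-positive: 547/610 = 89.7%  (generator fraction 90%)
cargo-load Gaussian: mu=68.1, sigma=15.0 (single-Gaussian description of the positive population)
brightness vs negative-call association: rho=-0.187 (p=3.3e-06)
```

The recovered positive fraction (89.7%) matches the generator's 90%; the
cutoff sits far below the load Gaussian (μ ≈ 68), i.e. in the regime where
the classification is driven by the cargo itself rather than noise. Fewer
objects than true vesicles are detected because nearby spots merge; merged
objects are brighter and virtually always cargo-positive, which is what
the weak brightness association reports.

The other `examples/` scripts demonstrate scene simulation, pixel-mask
co-localisation with the offset control, dilution-series removal
calibration, and the PMA / SILAC statistics. A thin CLI mirrors the
library:

```bash
vesiflux simulate --config scene.yaml --out scenes/ --seed 1
vesiflux objects --image scenes/scene.ome.tif --out results/
vesiflux pixelcoloc --image scenes/scene.ome.tif --signal streptavidin \
    --mask transferrin --offset-nm 500 --out coloc.csv
vesiflux calibrate dilution --table series.csv
vesiflux proteome silac --table ratios.csv --scale log2
vesiflux run --config run.yaml
```

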