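# sptcorral

Spatially resolved single-molecule binding kinetics on micropatterned
mobile/immobile ligand substrates.

## The problem

Receptor tyrosine kinases such as EphA2 cluster when their membrane-anchored
ligand (ephrinA1) is laterally mobile, and stay dispersed when the ligand is
grafted in place. Hybrid substrates present both configurations to a single
cell as a grid of micron-scale corrals: fluid supported-membrane corrals
("mobile", clusterable) alternating with polymer-grafted corrals
("immobile"). Single-molecule TIRF imaging of photoswitchable adaptors
(Grb2, SOS, NCK, N-WASP) then asks the quantitative question: *does receptor
clustering change how long a downstream molecule stays bound, and how often
one arrives?*

`sptcorral` is the complete analysis chain for such experiments, plus a
ground-truthed simulator of them:

* **synthetic** — corral layouts, Poisson binding events with
  two-exponential dwell mixtures, photobleaching, confined diffusion,
  camera-realistic movie rendering, ligand-channel rendering, and
  two-channel corral intensity datasets with configured fold-changes.
* **detection** — matched-filter spot detection with subpixel Gaussian
  refinement (vectorized over all candidates, with a two-emitter splitter
  for just-overlapping molecules), plus the single-molecule sanity checks:
  intensity-unimodality and single-step photobleaching.
* **tracking** — greedy nearest-neighbor linking, frame-quantized dwell
  times with censoring, sptPALM-style first-appearance localization images,
  MSD/confinement diagnostics.
* **regions** — corral segmentation from the ligand channel, mobile/immobile
  classification by ligand clustering, region assignment of trajectories.
* **kinetics** — survival curves, the two-order exponential decay fit
  `y = y0 + A1·e^(−t/τ1) + A2·e^(−t/τ2)`, photobleach controls, appearance-based
  association rates (K_on), paired per-cell statistics.
* **quantify** — background-subtracted corral intensities, signal/ligand
  ratios, recruitment heat maps, max/cumulative recruitment, nuclear ratios.
* **pipeline / CLI** — end-to-end runs from a single YAML/JSON config with
  reproducible seeds and JSON reports (`sptcorral simulate|detect|track|mask|fit|quantify|run`).

The comparison statistic throughout is **τ2**, the slower time constant of
the survival-curve fit (apparent K_off = 1/τ2), compared mobile-vs-immobile
*within* each cell — cell-to-cell variation is larger than the clustering
effect, so only the paired, side-by-side comparison resolves it.

## Worked example

```python
from sptcorral import run_simulated_experiment

report = run_simulated_experiment({
    "seed": 1,
    "simulation": {
        "dwell": {
            "mobile":   {"f1": 0.55, "tau1_s": 0.08, "tau2_s": 0.508},
            "immobile": {"f1": 0.55, "tau1_s": 0.08, "tau2_s": 0.451},
        },
        "bleach_rate_per_s": 0.1,
    },
})
for region in ("mobile", "immobile"):
    est = report["estimates"][region]
    print(region, round(est["tau2_s"], 3), est["n_tracks"])
```

prints

```
mobile 0.464 9966
immobile 0.442 9733
```

i.e. from ~10,000 simulated trajectories per region the pipeline recovers
apparent slow dwell constants of 464 ms (mobile) and 442 ms (immobile).
The configured truths are 508 and 451 ms; with the configured photobleach
rate of 0.1/s the *apparent* truths are 1/(1/0.508 + 0.1) = 483 ms and
1/(1/0.451 + 0.1) = 414 ms, so the mobile estimate is ~4% low and the
immobile ~7% high at this single seed — consistent with the per-region
sampling spread of a single field. Bleaching is reported, never
subtracted: the experimental comparison is of apparent dwell times under
identical illumination.

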