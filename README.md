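# curvestats

Tools for studying **contours defined by constant curvature** — both how
well human observers detect them, and how often they occur in images.

The package has two coupled halves:

1. **Psychophysics.** Contour-in-noise detection stimuli: an 8°×8° field of
   256 Gabor micro-patterns on a 16×16 grid (one element centroid per 0.5°
   cell, so local density never reveals the target), containing a train of
   six elements whose central four turn by a constant *curvature angle*
   α ∈ {0…40°} per step. The two *end elements* sit in a direction θₑ
   relative to the terminal element's orientation (positive = toward the
   curvature), with their own orientation equal to that direction.
   Proportion-correct data from a two-interval forced-choice task are
   summarised per curvature angle by a Gaussian tuning curve

       Y = A · exp(−0.5 (X − M)² / SD²)

   where A is peak proportion correct, M the end direction of best
   detection and SD the tuning width. A simulated binomial observer stands
   in for human subjects.

2. **Image statistics.** Oriented edge elements are extracted with
   log-Gabor filters — a radial filter H(r) = exp(−5.77 (ln(r/f_c)/B₀)²)
   with peak f_c = 0.1 cycles/px and a 1.5-octave half-amplitude bandwidth
   supplies zero-crossing candidates, and an oriented quadrature bank
   (every 10°, 40° orientation bandwidth) supplies orientation energy. A
   greedy unguided search then maps chains of exactly four edge elements
   that are pairwise *continuous* (θ = 2φ, the cocircularity rule, ±5°),
   equally spaced (±1/5) and constantly turning (±5°), and records the
   orientations of *end elements* that continue each mapped chain. The
   statistics of those end orientations — per curvature class and
   inter-element-distance bin — are the output: normalised distributions,
   Gaussian fits, and an exponential trend M = S·exp(K·X) of peak
   orientation versus curvature angle. A synthetic corpus generator plants
   ground-truth chains so the whole pipeline is testable offline.

The analysis stages follow the scikit-learn estimator API
(`GaussianTuningFitter.fit/predict`, `LogGaborEdgeDetector.transform`,
`ConstantCurvatureMapper.transform`) and compose with sklearn tooling;
module-level functions wrap them for one-off use.

## Worked example

Run the image half end to end on a 12-image synthetic corpus (planted
chains, more low- than high-curvature, continuation elements at the
curvature step):

```python
from curvestats.pipeline import RunConfig, run_image_pipeline

summary = run_image_pipeline(RunConfig(out_dir="run", seed=1,
                                       synth={"n_images": 12}))
print(summary["counts"].to_dict())
print(summary["peaks"])
print(summary["trend"])
```

prints

```
{0: 24, 10: 24, 20: 12, 30: 10, 40: 6}
{0: 0.0, 10: 10.0, 20: 20.0, 30: 30.0, 40: 40.0}
TrendFit(model='exponential', parameters={'S': 6.683861470157526, 'K': 0.0460675465100815}, r2=0.9284468493983451, converged=True)
```

The counts decrease from low to high curvature (low-curvature contours
are more common, as planted); each curvature class's end-element
orientation distribution peaks at the planted continuation offset (here
exactly the curvature step, so the peaks sit at 0…40°); and the peak-vs-
angle trend is well fit by exponential growth. `run/` contains the contour
and end-element tables (CSV), the distribution table, a JSON fit summary,
and a provenance manifest with the exact configuration and library
versions.

The psychophysics half, simulating six observers on the 50-condition grid
(5 curvature angles × 10 end directions, 200 trials each) and fitting the
tuning curve per angle:

```python
from curvestats.pipeline import RunConfig, run_psychophysics_pipeline

res = run_psychophysics_pipeline(RunConfig(out_dir="psy", seed=1,
                                           experiment=1, n_observers=6))
print(res["group"].round(3))
```

```
                       A       M      SD     r2  n_degenerate
contour_angle_deg
0                  0.902   0.014  62.762  0.961             0
10                 0.833   7.791  61.944  0.925             0
20                 0.776  14.065  60.785  0.836             0
30                 0.674  21.382  67.141  0.762             0
40                 0.588   5.042  76.533  0.678             5
```

Detection amplitude A falls as the contour curves more; the best end
direction M tracks (but lags) the curvature angle; the 40° class is near
chance and broadly tuned, so most of its per-observer fits come back
flagged as degenerate and are excluded from the group means.

A `curvestats` CLI exposes each stage (`stimgen`, `psyfit`, `edges`,
`map`, `stats`, `synth`, `run-images`, `run-psy`); see `curvestats --help`.

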