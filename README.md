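# linacqa

Beam-model QA for medical linear accelerators: phase-space characterization
and water-phantom dose comparison.

When the head geometry of a clinical linac is not available, Monte Carlo
dose calculations must start either from vendor-distributed phase-space
files or from a *surrogate* geometry of a similar machine. Judging whether
a surrogate beam model reproduces a reference beam requires two kinds of
evidence:

1. **Phase-space agreement** — do the particle distributions on a tally
   plane below the target match? `linacqa` bins phase-space records into
   energy spectra in concentric rings about the central axis (CAX), angular
   distributions per unit solid angle, and the radial planar energy
   fluence, and scores any two binned distributions with the
   *percentage of agreement*

   ```
   PA = 100 · [ 1 − δ / max(A₁, A₂) ],     δ = Σ |f₁ − f₂| · Δbin,
   ```

   where A₁, A₂ are the areas under the two distributions.

2. **Dose agreement** — do the resulting water-phantom dose distributions
   match measurement-like reference scans? `linacqa` extracts depth-dose
   curves (normalized to their maximum) and lateral profiles (normalized to
   the CAX value) from 3D dose grids by trilinear interpolation at the
   reference points and applies the gamma index

   ```
   γ(r) = min over p of sqrt( ‖p − r‖²/DTA² + (D_eval(p) − D_ref(r))²/ΔD² ),
   ```

   with the standard commissioning criteria 2% (global) / 2 mm; a point
   passes when γ ≤ 1 and the gamma pass rate (GPR) is the percentage of
   passing points. Output factors — CAX dose at 10 cm depth relative to the
   10 × 10 cm² field — complete the commissioning picture.

Because clinical phase-space files and vendor reference dosimetry are
customer-restricted, the package ships a synthetic generator
(`linacqa.synthetic`) that emulates the *statistical structure* of both: a
photon phase space from a point-like bremsstrahlung source with a circular
Gaussian focal spot and a radially softening spectrum, and analytic
water-phantom dose with buildup + attenuation depth dose, error-function
penumbrae, and optional Gaussian noise mimicking Monte Carlo statistical
uncertainty. Every stage of the pipeline is exercised end to end on these
synthetic inputs.

## Worked example

```python
import numpy as np
from linacqa import (beam_preset, generate_phasespace, pa_matrix,
                     DoseModel, generate_dose_grid, generate_rbd_like_dataset,
                     gamma_points, aggregate_gpr)
from linacqa.synthetic import field_grid_spec

# --- phase-space comparison: a 15 MV beam vs a deliberately discrepant one
base = generate_phasespace(beam_preset("15MV"), 500_000, seed=1)
disc = generate_phasespace(beam_preset("15MV-discrepant"), 500_000, seed=2)
print(pa_matrix(base, disc).round(1).to_string(index=False))
```

```
 [0-1]  [1-2]  [2-3]  [3-4]  [4-5]  [5-6]  [6-7]  [0-6]
  72.1   82.6   87.1   89.7   90.3   91.2   92.3   94.5
```

The discrepant preset injects 40% extra low-energy fluence within 1 cm of
the CAX; the PA in the inner ring drops the most (a self-comparison scores
100 in every region, and at these desk-scale statistics the remaining
spread is counting noise).

```python
# --- dose commissioning comparison on self-consistent synthetic data
models = {f: DoseModel(field_side=f) for f in (3.0, 10.0, 30.0)}
references = generate_rbd_like_dataset(models, depths=(5.0,), z_max=30.0)
results = []
for ref in references:
    dm = models[ref.field_cm]
    origin, voxel, dims = field_grid_spec(dm, z_max=32.0)
    grid = generate_dose_grid(dm, origin, voxel, dims, seed=0,
                              target_mean_rel_unc=0.004)
    res = gamma_points(ref, grid)
    results.append(res)
    print(f"field {ref.field_cm:4.0f} cm  {ref.axis:9s}  "
          f"GPR(2%,2mm) = {res.gpr:6.2f}%  ({res.n_points} points)")
print(aggregate_gpr({"6MV": results}).to_string(index=False))
```

```
field    3 cm  depth      GPR(2%,2mm) = 100.00%  (95 points)
field    3 cm  crossline  GPR(2%,2mm) = 100.00%  (51 points)
field   10 cm  depth      GPR(2%,2mm) = 100.00%  (95 points)
field   10 cm  crossline  GPR(2%,2mm) = 100.00%  (65 points)
field   30 cm  depth      GPR(2%,2mm) = 100.00%  (95 points)
field   30 cm  crossline  GPR(2%,2mm) = 100.00%  (107 points)
beam  n_fields  mean_gpr  std_gpr
 6MV         6     100.0      0.0
```

A grid and reference set generated from the same dose model pass everywhere
even with 0.4% statistical noise; a 3% output error on the common dose
scale drives the in-field plateau pass rate to 0.

The same workflows are available from the shell:

```sh
linacqa synth --preset 6MV --histories 100000 --seed 1 --dose --rbd --out run/
linacqa ps-compare run/6MV.phsp run/6MV.phsp --out cmp/
linacqa dose-compare --ref run/reference_profiles.csv \
    --grid 10=run/field10 --of --out cmp/
```

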