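# tumordecay

How fast does the immune system destroy a solid tumor?  `tumordecay`
implements a saturating *fractional cell kill* law for lysis of tumor
cells by cytotoxic lymphocytes,

```
dT/dt = -K(E, T) · T^ν,      K(E, T) = d·E^λ / (s·T^ν + E^λ)
```

a Hill-type rate in both the tumor population `T` and the effector
population `E` (both exponents ≤ 1), together with the geometric decay
regimes it predicts and a cellular-automaton experiment that tests them:

* **linear decay** `dT/dt = -d·E₀^λ/s` when a small effector rim faces a
  large tumor (one effector ≈ one lysed cell per hour);
* **parabolic decay** `dT/dt = -d·T^(1/2)` when a 2-D tumor is fully
  wrapped by effectors and loses one surface layer per kill cycle
  (`d = 2√π·c` for erosion at radial speed `c`); `ν = 2/3` for a 3-D
  ball, `ν = 1` (exponential) for well-mixed/infiltrated populations;
* the `δ(t)` correction for non-circular shapes via equivalent-area disks.

It is written for modellers in mathematical oncology who want a compact,
reproducible testbed for tumor–immune decay kinetics: ODE integration and
closed forms (`kinetics`), analytic and raster erosion (`geometry`), a
two-phase growth + frozen-tumor lysis automaton with spherical / papillary
/ filamentary morphology presets (`automaton`), a single-lymphocyte
random-walk toy model (`walker`), and power-law vs exponential trajectory
fitting (`fitting`), all behind a `tumordecay` CLI.

## Worked example

Grow a compact ("spherical") tumor to ~2000 cells on a 120×120 grid,
wrap it completely with immune cells (γ = 2π), run the lysis, and ask
which decay law fits:

```
$ tumordecay grow --preset spherical --n 120 --target 2000 --seed 1 --out grid.txt
{"area": 2000.0, "perimeter": 206.17, "isoperimetric_ratio": 0.591, "steps": 37, ...}

$ tumordecay lyse --grid grid.txt --gamma 2pi --preset spherical --seed 2 --out series.csv
INFO tumordecay: placed 1165 immune cells over gamma=6.2832 rad
INFO tumordecay: lysis finished after 32 hours (truncated=False)

$ tumordecay fit --series series.csv
points fitted      : 29
power law  T'=-dT^v: d = 2.042, nu = 0.5427, SSE = 3242.02
exponential T'=-dT : d = 0.08367,            SSE = 214892
SSE ratio (pow/exp): 0.01509
preferred family   : power_law
```

Reading the output: the tumor of 2000 cells is eradicated in 32 hours;
the power-law fit recovers an exponent near 1/2 — the parabolic,
surface-erosion signature (small tumors at this toy scale carry a few
hundredths of upward bias) — while the exponential law misses the
trajectory by a factor of sixty in squared error.  The same
pipeline with `--gamma pi/6` (a thin arc of effectors) produces a
near-linear decay instead, and the `filamentary` preset decays several
times faster than the spherical one at equal size (its surface-erosion
rate constant is ~3x larger, reflecting the larger contact surface).

The library API mirrors the CLI:

```python
import numpy as np
from tumordecay import run_experiment, fit_power_law

series = run_experiment("spherical", gamma=2 * np.pi, seed=1,
                        n=120, target_size=2000)
print(fit_power_law(series))   # FitResult(family='power_law', nu≈0.5, ...)
```

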