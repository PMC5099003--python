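# cuffshear

Wall-shear-stress (WSS) metrics of atherogenic flow for the mouse carotid
cuff model, as a tested Python pipeline.

A tapered constrictive cuff (lumen 500 µm at the inlet tapering to 250 µm at
the outlet, a 75% areal stenosis) placed around one carotid artery creates
three distinct flow disturbances: low WSS upstream, high WSS inside the
cuff, and oscillatory/multidirectional WSS downstream, where a time-varying
vortex drives flow reversal. `cuffshear` quantifies these disturbances from
time-resolved WSS vector fields **τ**(x, tᵢ) sampled on a triangulated lumen
surface over one cardiac cycle, segregates the cuffed vessel into four
regions (upstream outside the plaque, upstream plaque, cuff, downstream)
and runs the paired instrumented-vs-control cohort statistics. It is aimed
at researchers in vascular biomechanics who post-process CFD or synthetic
WSS fields on vessel surfaces.

## The six metrics

With n exported instants over the cycle (uniform grid, equal weights) and
τᵢ the WSS vector at instant i:

| metric | definition | captures |
|---|---|---|
| TAWSS | (1/n)·Σ‖τᵢ‖ | shear magnitude (Pa) |
| OSI | ½·(1 − ‖Στᵢ‖ / Σ‖τᵢ‖) | 180° flow reversal (0–0.5) |
| RRT | 1/‖(1/n)·Στᵢ‖ | near-wall residence (Pa⁻¹) |
| tSS | (1/n)·Σ|τᵢ·q|, q ⊥ mean-WSS direction in the tangent plane | multidirectionality (Pa) |
| SAD | mean angle between a node's WSS vector and its neighbours' | spatial direction change (rad) |
| LSI / HSI | max(0, (low − TAWSS)/low), max(0, (TAWSS − high)/TAWSS) | atherogenically low / high shear (0–1) |

The LSI/HSI thresholds are calibrated from the contralateral control vessel,
assumed to carry non-atherogenic flow: with m and s the mean and sample SD
of ln(TAWSS_control),

    low  = exp(m − 0.67·s)        high = exp(m + 0.67·s)

i.e. the bottom and top 25% of a log-normal control distribution. Thresholds
scale with the animal, so the indices are scale-invariant across species.

Because mouse-specific micro-CT geometry and a Navier–Stokes solution are
not reproducible at desk scale, the package ships a first-class synthetic
generator: straight paired carotids (622/594 µm diameter, 10 mm long), a
two-harmonic pulsatile inlet waveform (8 Hz, 300 steps per cycle, every 10th
step exported → 30 instants), a quasi-steady Poiseuille closure
|τ|(s, t) = 4µQ(t)/(πR(s)³) (valid at Re ≈ 40), a parametric downstream
vortex producing reversal and circumferential shear, and log-normal spatial
TAWSS heterogeneity. See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import cuffshear as cs

cohort = cs.synth_cohort(7, seed=0)          # 7 mice, paired vessels
analysis = cs.analyze_cohort(cohort)         # metrics -> regions -> stats
s = analysis.summary
print(s[s.metric.isin(["OSI", "tSS", "LSI", "HSI"])
        & s.region.isin(["upstream_plaque", "downstream"])]
      [["region", "metric", "instrumented_mean", "control_mean",
        "p_one_sided", "stars"]].round(3).to_string(index=False))
```

prints

```
         region metric  instrumented_mean  control_mean  p_one_sided stars
upstream_plaque    OSI              1.000           1.0        0.500
upstream_plaque    tSS              1.000           1.0        0.500
upstream_plaque    LSI              5.962           1.0        0.000   ***
upstream_plaque    HSI              0.283           1.0        1.000
     downstream    OSI             42.625           1.0        0.000   ***
     downstream    tSS             21.956           1.0        0.000   ***
     downstream    LSI             11.380           1.0        0.000   ***
     downstream    HSI              1.114           1.0        0.012     *
```

Values are region means of display-normalized metrics, floored at 0.005 and
divided by the cohort-mean control value, so every control sits at 1 and an
instrumented value is a fold factor over control. Upstream of the cuff only
the magnitude metric LSI is elevated (directional metrics are
indistinguishable from control, p = 0.5); downstream, reversal (OSI) and
multidirectionality (tSS) dominate — the signature of the cuff model.
`p_one_sided` is the one-tailed two-sample t-test for instrumented >
control across the n = 7 mice.

The same pipeline is available from the shell:

```
cuffshear run-all --seed 0 --out results/
cuffshear simulate --seed 1 --out sim/        # STL + WSS field CSVs only
cuffshear metrics --mesh v.stl --field f.csv --out metrics.csv
cuffshear enface --mesh v.stl --metrics metrics.csv --metric OSI --out grid.csv
```

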