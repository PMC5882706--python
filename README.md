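# pestspread

Stochastic simulation of invasive-pest spread across a farm landscape,
with post-hoc evaluation of surveillance strategies.  Built for
biosecurity modellers asking a concrete design question: **does the way
an organism disperses change how we should search for it?**  The package
lets you spread the same invasion under thin-tailed (exponential) and
fat-tailed (leptokurtic Weibull) dispersal kernels, overlay sampling
schemes of varying arrangement, density, frequency and per-visit
detection probability, and compare when the invasion is found and how
far it has gone by then.

## Model in brief

The landscape is a raster of 1 × 1 m pixels: a 5 × 5 block of
100 × 100 m suitable fields separated by 2 m unsuitable divisions inside
a 50 m unsuitable buffer.  An invasion starts at one uniformly random
suitable pixel.  Each month, a pixel colonized a months ago produces

    p(a) = p_max · (1 − 2^(−(a − t₀)/(t₅₀ − t₀)))   for a > t₀  (else 0)

propagules (p_max = 10⁴, t₀ = 5, t₅₀ = 15 months); each propagule
disperses isotropically with a distance drawn from a kernel specified by
its median d₅₀ and 99th-percentile d₉₉ distances, and establishes with
probability p_estab = 0.01 if it lands on a suitable uncolonized pixel.
Propagules clearing the buffer are *escapes* from the surveyed area.
Surveillance points are checked on a periodic schedule; an infested
sampled pixel is detected with probability p_detect per visit.  At first
detection the model records the five outcome measures: detection time
T, maximum spread distance, infested area, fields infested, and
cumulative escapes.

Five kernel presets span dispersal distance and kurtosis — `Exp`,
`Exp+` (exponential, d₉₉ = 5 and 10 m), `Wei`, `Wei-`, `Wei+` (Weibull,
shape k < 1; `Wei+` is extremely fat-tailed with d₅₀ = 0.5 mm but
d₉₉ = 5 m).  Fat tails produce satellite foci ahead of the front and
are the only route past the buffer.

## Worked example

```python
import pestspread as ps

wei = ps.fit_kernel("weibull", d50=0.05, d99=5.0)
print(f"Wei kernel: shape k = {wei.shape:.4f}, scale = {wei.scale:.4f} m, "
      f"P(jump > 50 m) = {float(ps.tail_probability(wei, 50)):.2e}")

cfg = ps.ExperimentConfig(kernels=("Wei", "Exp"), replicates=10, t_max=400,
                          arrangements=("grid",), densities=(2,),
                          frequencies=(1,), p_detects=(0.75,), root_seed=42)
table = ps.run_experiment(cfg)          # one row per replicate × scheme
summary = ps.summarize(table)
cols = ["kernel", "output", "mean", "se", "median"]
print(summary[summary.output.isin(["T", "max_dist", "escapes"])][cols]
      .round(2).to_string(index=False))
```

prints

```
Wei kernel: shape k = 0.4112, scale = 0.1219 m, P(jump > 50 m) = 7.00e-06
kernel   output  mean   se  median
   Exp        T 70.90 6.20   77.00
   Exp max_dist 46.79 4.39   50.89
   Exp  escapes  0.00 0.00    0.00
   Wei        T 41.20 2.56   39.50
   Wei max_dist 65.19 6.14   63.28
   Wei  escapes  0.00 0.00    0.00
```

Read: under an identical grid of 2 points/field visited monthly with 75%
per-visit detection, the fat-tailed `Wei` invasion is found ~30 months
*earlier* than the thin-tailed `Exp` one (its satellites hit sampled
pixels sooner) — yet it has already spread *further* by detection time
(65 m vs 47 m mean maximum distance).  Early detection and contained
spread are different objectives.  At this density neither kernel put a
propagule past the 50 m buffer; at 0.5 points/field `Wei+` averages
escapes in the hundreds.

## Command line

```sh
pestspread simulate  --config study.yaml --out-dir out   # spread records
pestspread overlay   --config study.yaml --out-dir out out/Wei_rep0000 ...
pestspread summarize out/outcomes.csv --out-dir out --plots
```

The YAML config has sections `landscape`, `population`, `kernels`,
`surveillance`, `experiment`; an empty file reproduces the full baseline
factorial (5 kernels × 100 replicates × 3 arrangements × 7 densities ×
7 frequencies × 4 detection probabilities).  A run manifest with all
derived seeds makes every output reproducible byte-for-byte.

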