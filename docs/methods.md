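# Model and methods

`pestspread` simulates the early spread of an invasive organism across a
rasterized farm landscape and evaluates how quickly different
surveillance strategies would detect it, and at what cost in spread.
This note documents the model, its parameters, the numerical choices,
and what the simulations do and do not represent.

## Landscape

The landscape is a square raster of `pixel_size` × `pixel_size` pixels
(default 1 × 1 m) containing a `fields_per_side` × `fields_per_side`
block of square fields of suitable habitat (default 5 × 5 fields of
100 × 100 m = 250 000 suitable pixels), separated by narrow unsuitable
divisions (default 2 m, e.g. roads or windbreaks) and surrounded by an
unsuitable buffer (default 50 m).  The pest can establish only inside
fields.  A propagule landing beyond the outer edge of the buffer is an
*escape* — it has left the surveyed area and is counted but never
re-enters the simulation.

With the default components the domain side is
5·100 + 4·2 + 2·50 = 608 m.  Published descriptions of comparable farm
layouts sometimes quote slightly different totals than their stated
components imply; every width here is configurable (a 53 m buffer, for
example, gives a 614 m side), and because the thin-tailed kernels'
survival beyond even 40 m is ≲ 1e−16, a few metres of buffer are
immaterial to every reported quantity.

Coordinates are continuous, origin at the lower-left corner; pixel
(i, j) covers [i, i+1) × [j, j+1) m and acts through its centre.  Field
ids run 1..n² row-major from the lower-left field.

## Population dynamics

Each colonized pixel produces propagules once per timestep (a month) as
a deterministic function of its age a (months since colonization):

    p(a) = round( p_max · (1 − 2^(−(a − t_0)/(t_50 − t_0))) ),  a > t_0
    p(a) = 0,                                                   a ≤ t_0

Defaults: `p_max` = 10 000 propagules/generation, `t_0` = 5 months
(onset of reproduction), `t_50` = 15 months (half-maximum production),
`p_estab` = 0.01 (probability that a propagule landing on suitable
habitat founds a new infestation).  The curve is the simplest monotone
saturating form anchored exactly at the two stated landmarks — zero
through `t_0`, half of `p_max` at `t_50`, saturating at `p_max`.  The
within-pixel maturation curve is a genuine degree of freedom of this
model class (different monotone curves through the same landmarks change
early spread rate by a few percent); it is isolated behind
`propagule_count` so alternatives can be swapped without touching the
engine.  A nominal spread rate `r_0` (1 m/year) is carried in the
parameter set for configuration completeness but does not enter the
production curve: realised spread rate is an emergent property of
dispersal and establishment.

Pixels carry no population size beyond their age: no mortality, no
density dependence beyond the saturating curve, no Allee effects, and
colonization is absorbing.

## Dispersal kernels

A kernel is the distribution of the distance a propagule travels;
direction is uniform and independent (passive, isotropic dispersal).
Kernels are parameterized by two quantiles, the median `d50` and the
99th percentile `d99`, and solved in closed form:

    exponential:  F(x) = 1 − e^(−x/λ),            λ = d99/ln 100
    Weibull:      F(x) = 1 − e^(−(x/λ)^k),        k = ln(ln .01/ln .5)/ln(d99/d50),
                                                  λ = d50/(ln 2)^(1/k)

The exponential family has one parameter, so d99/d50 = ln .01/ln .5 ≈
6.64 is fixed; Weibull fits require a fatter ratio (k < 1, the
leptokurtic regime).  The five named presets:

| preset | family      | d50 (m) | d99 (m) | k      | λ (m)  |
|--------|-------------|---------|---------|--------|--------|
| Exp    | exponential | 0.7526  | 5       | —      | 1.0857 |
| Exp+   | exponential | 1.5051  | 10      | —      | 2.1715 |
| Wei    | Weibull     | 0.05    | 5       | 0.4112 | 0.1219 |
| Wei−   | Weibull     | 0.025   | 2.5     | 0.4112 | 0.0610 |
| Wei+   | Weibull     | 0.0005  | 5       | 0.2056 | 0.0030 |

Distances are sampled by inverse-CDF transform (exact; no rejection).
Shrinking d50 at fixed d99 fattens the far tail: beyond 50 m the Wei+
survival is ~6e−4 against ~1e−20 for Exp, which is why only Weibull
invasions ever escape the buffered farm and why they throw satellite
foci beyond the main front.

## Spread engine

Monthly synchronous updates: every pixel colonized before the current
step produces `p(age)` propagules from the state at the start of the
step; each propagule independently establishes (probability `p_estab`)
if it lands on a suitable, uncolonized pixel; landings on unsuitable,
already-colonized, or source pixels are lost; landings outside the
domain are escapes.  A pixel colonized this step first reproduces in a
later step.  Within a step, a pixel colonized by several propagules
keeps the single colonization time, so results are order-independent
and bit-reproducible from the seed.

Two *exact* optimizations make 100-replicate studies desk-scale:

1. **Establishment thinning.**  Only the Binomial(n, p_estab) candidate
   subset is dispersed, and every candidate landing on suitable
   uncolonized habitat establishes.  Per destination pixel this is the
   same two-stage Bernoulli thinning as dispersing all n and thinning at
   the landing site; the equivalence is verified by a chi-square test
   against the exhaustive engine (`thinned=False`).  Escape counts are
   therefore counts of dispersing *candidates*; the exhaustive switch
   disperses every propagule and so reports ~1/p_estab more escapes.
2. **Clearance pruning.**  A draw from source i shorter than the
   distance from i to the nearest suitable-uncolonized pixel (or the
   domain edge) lands somewhere it would be discarded.  Each source is
   thinned by P(r ≥ trunc_i) and the remainder sampled from the
   tail-conditioned kernel, with trunc_i a safe lower bound on that
   clearance from a distance transform refreshed every 10 steps.
   Colonization only removes targets, so clearances only grow and a
   stale map stays a valid lower bound.  This is what keeps saturated
   interiors (which would otherwise re-disperse ~100 candidates per
   pixel per month into their own patch) essentially free.

Default horizon `t_max` = 400 months, the upper end of the 200–400
range used for runs of this design, so that slow, sparsely surveyed
invasions still reach detection; replicates undetected at the horizon
are flagged rather than censored silently.

## Surveillance and detection

A scheme is (arrangement, density, frequency, p_detect).  Densities
0.5–25 points/field; every arrangement places round(density · 25)
points so arrangements are comparable at equal effort:

* **grid** — each field split into `density` near-square congruent
  cells, one point per cell centre.  Density 0.5: one centre point per
  field of a checkerboard half of the fields, the half alternating
  between replicates.
* **random** — same per-field counts, locations uniform within each
  field, redrawn each replicate.
* **strategic** — border-protecting: one centre point per interior
  field, the remaining budget evenly spaced along the outermost
  suitable pixel ring of the border fields.

Visits occur at months {1, 1+f, 1+2f, …}: surveillance starts when the
program starts, and a lower frequency stretches the interval between
visits.  (The alternative phase — first visit at month f — suppresses
almost the whole monthly-vs-yearly difference in detection time for
fast-detected kernels and is inconsistent with the reported frequency
effects; see the replication notes below.)  At each visit, each point
whose own pixel is infested triggers an independent Bernoulli(p_detect)
trial — no detection radius, no trap memory, no removal.  The first
visit with a success is the detection time T, at which the five outcome
measures are recorded: T, maximum Euclidean distance of any infested
pixel from the incursion pixel, infested area (m²), number of fields
with any infested pixel, and cumulative escapes.

Given a fixed spread history with k points infested from month m under
monthly visits, T − m + 1 is geometric with success probability
1 − (1 − p_detect)^k; this closed form anchors the overlay's unit tests,
and coupled-uniform tests verify that raising p_detect, density or
frequency never delays detection.

## Experiment driver

`run_experiment` simulates each replicate's spread once per kernel and
overlays every scheme of the factorial grid on it, each scheme consuming
its own RNG sub-stream derived from (root seed, replicate, stream
label).  Overlays run while the invasion grows and the replicate stops
as soon as every scheme has detected — distributionally identical to
serializing the record and re-checking it per scheme (asserted in the
tests on shared streams), and the only practical way to avoid simulating
saturated landscapes for hundreds of post-detection months.

Summaries report, per group and outcome: mean, standard error
(sd/√n), median, quartiles (linear interpolation), whisker range
(min/max), and an outlier count using the points-beyond-1.5·IQR-from-
the-*median* rule (a nonstandard box-plot rule retained for fidelity;
`median_rule=False` gives conventional Tukey fences).  Replicates
undetected at the horizon (which occur only at p_detect = 0.01) are
excluded from moments and reported as a separate not-detected fraction.

## Replication notes and problem sizes

`scripts/acceptance.py` reruns the grid-surveillance cells behind the
published in-text means at 80 replicates per kernel (the original study
used 100); the acceptance tests use 30.  At these sizes the whole
recomputation takes a few minutes on one CPU.  Reproduced quantities
include the solved kernel parameters (exact), detection times for Wei−
at the extreme densities, maximum spread distance for Wei+ and Exp at
the lowest density, escapes for Wei+ across densities, and the yearly-
visit detection time for Exp+ — each compared within three published
standard errors rescaled by √(100/n).

One published quantity does not reproduce under the stated definitions:
the mean number of fields infested at detection.  For Wei+ at the lowest
density this package computes ~17–19 fields where ~5.5 was reported —
yet the co-measured outputs of the same detection events (max distance
~390–430 m, area ~12 000 m², escapes ~140–190) all match.  A max spread
distance of ~400 m across a 508 m field block under a
count-fields-with-any-infested-pixel rule cannot coexist with ~5.5
fields; the same tension appears for the thin-tailed kernels (a
reported ~64 m spread radius from an origin uniform in a 100 m field
nearly always crosses the 2 m division, yet <2 fields were reported).
The field count here follows the stated any-infested-pixel definition;
the discrepancy is documented rather than fitted.

## What the generator does not emulate

The landscape is binary (suitable/unsuitable) with no habitat-quality
gradients, host maps, or spatial heterogeneity; dispersal is passive and
isotropic with no wind, vectors, or anisotropy; there is no mortality,
eradication, false-positive detection, or economic accounting.  Passing
tests show that the *model as specified* behaves and reproduces as
documented — not that any real pest disperses by these kernels.
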