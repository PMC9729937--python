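# Methods

## The model

Two cell populations share one compartment: chemosensitive cells `N_s` and
chemoresistant cells `N_r`, both real-valued (the model is deterministic;
no demographic stochasticity). Over one scaled treatment interval (t = 1)
each grows exponentially with log-increment `a_s` and `a_r`. Chemotherapy
at dose `x` acts only on sensitive cells, multiplying them by the viability
`V(x)` of a decreasing Hill curve

    V(x) = bottom + (top − bottom) / (1 + (x / EC50)^h),

with defaults `top = 1`, `bottom = 0` (viability is a survival fraction).
Resistant cells are assumed fully insensitive at modelled doses — the
strongest simplification in the model: real resistant lines retain partial
sensitivity, so crossover and critical doses computed here are bounds, not
point predictions, for weakly resistant clones.

Splitting a cumulative dose `x` into `n` equal administrations within the
same interval gives the closed form

    N_s' = V(x/n)^n · e^{a_s} · N_s,      N_r' = e^{a_r} · N_r.

Growth appears once per interval. Compounding it per sub-interval,
`(V(x/n)·e^{a_s/n})^n`, expands to exactly the same expression, so there is
no "interleaved" variant to toggle. Multi-interval courses compose the
one-interval update (`repeats` argument).

### Derived metrics

* **Gain** — ratio of an n-dose regimen's outcome to the 1-dose regimen's
  at the same cumulative dose and initial state, for both the final total
  and the final resistant fraction. `gain(n=1) ≡ 1`.
* **Crossover dose** `x*` — the positive root of `V(x/n)^n = V(x)`. Because
  the resistant term is regimen-independent it cancels from the total-cell
  ratio at `x*`; the crossover depends only on the curve. For
  `h = 2, top = 1, bottom = 0, n = 2`: `(1 + u/4)^2 = 1 + u` with
  `u = (x/EC50)^2` gives `u = 8`, i.e. `x* = EC50·√8`. For `h ≤ 1` the
  AM–GM-type inequality `(1 + u/n)^n ≥ 1 + u` means fractionation never
  kills more, and the root-finder reports no crossover.
* **Critical concentration** — the dose at which the final population is
  half resistant. The final resistant fraction is monotone in dose, so
  bisection applies. Closed-form check for `top = 1, bottom = 0, n = 1`:
  `V(x) = (N_r/N_s)·e^{a_r − a_s}`, i.e. for a 1:1 seed
  `x = EC50·(e^{a_s − a_r} − 1)^{1/h}`. With `N_r = 0`, or with a bottom
  plateau that preserves a sensitive majority at saturating dose, the
  half-resistant state is unreachable and a dedicated error is raised.
* **Collateral trade-off** — healthy tissue is a purely sensitive
  population with its own Hill curve (for doxorubicin on mammary epithelial
  cells, EC50 = 0.052 uM, ~60-fold below the tumor line's 3.2 uM) and
  growth rate. Reported per regimen: drug-only surviving fraction
  `V_h(x/n)^n`, healthy count, and signed relative differences
  `(value(n) − value(1))/value(1)` against the single-dose baseline at the
  same cumulative dose.

### Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `EC50` | half-effect concentration (uM) | 3.2 (tumor), 0.052 (healthy) | fitted/literature values for doxorubicin used throughout the tests |
| `h` | Hill coefficient | 2 | steepness of the measured tumor response; `h > 1` is what makes a crossover exist |
| `a_s` | sensitive log-growth per interval | 0.2 in examples | interval is scaled, so only `a_s − a_r` matters for the critical dose |
| `a_r / a_s` | resistant growth ratio | 0.2 | resistant colonies expand markedly slower; the ratio is applied to the exponential rate (the natural reading of "20% of the sensitive growth rate" in this non-spatial model, even though the original measurement was a radial expansion slope) |
| `top`, `bottom` | viability plateaus | 1, 0 | survival-fraction interpretation; fits may relax both within [0, 1] |

## Fitting

`fit_hill` is unweighted nonlinear least squares on the viability scale
(`scipy.optimize.curve_fit`), initialised at `top = max(v)`,
`bottom = min(v)`, `ec50 =` dose with mean viability nearest the
half-range, `h = 1`; bounds `h ∈ (0, 10]`, `ec50 ∈ (0, 10·max dose]`,
plateaus in [0, 1]. This is robust for 6–10-point plates with a few
replicates. The Hill coefficient and/or both plateaus can be fixed; fixing
reduces the minimum number of distinct doses required (4 free parameters
need 4 distinct doses). Viability values above 1 or below 0 are kept by
default — they carry plateau information; `clip_negative` truncates at 0 on
request. `ic50` is the *absolute* 0.5-viability crossing,
`EC50·((top − 0.5)/(0.5 − bottom))^{1/h}`, which equals `EC50` only for
full plateaus.

MTT normalisation: per-well signal = OD570 − OD690; viability = signal /
mean(control-well signals), so control wells average to exactly 1. A
non-positive control mean invalidates the plate. No plate-effect
correction or outlier rejection is attempted.

## Root finding and grids

All scalar roots (crossover, critical dose) use bisection: the relevant
functions are monotone, so a bracketing sign change guarantees the root.
Bracket `[10⁻⁶, 10³]·EC50` (critical-dose search doubles an upper bound
from `EC50` instead), relative tolerance `10⁻⁹`. The crossover equation is
solved on the log-survival scale, `n·ln V(x/n) − ln V(x)`, for
conditioning. Default dose grids in examples are log-spaced.

## Synthetic data

The generator defines the conditions under which the pipeline is tested:

* **Viability plates** — `V(dose) + N(0, σ)` per replicate; σ = 0.05 with
  3 replicates and 8 log-spaced doses is the plate-noise condition for
  recovery tests (EC50 recovered within 15%).
* **Radial growth** — colony radius is exactly linear in time plus optional
  Gaussian noise; resistant lines get a 0.2× expansion rate. Negative rates
  are allowed; radii are floored at 0 with a flagged record.
* **Colony images** — the initial footprint is a disc whose area is
  (cell count)/(areal density), i.e. diameter ∝ √N — the simplest model
  consistent with an over-2× diameter increase from 10K to 50K seeded
  cells. Cells are anti-aliased constant-radius discs at uniformly random
  positions (overlaps allowed, no per-cell segmentation intended); the
  nuclei channel renders every cell, the marker channel sensitive cells
  only; constant background plus Gaussian noise, 16-bit range. Geometries:
  `scattered` (both populations uniform over the footprint),
  `subcolony_center` and `subcolony_edge` (resistant cells confined to a
  sub-disc sized by the sub-colony cell count at the same density; the
  edge sub-disc centre sits at 0.8× the footprint radius, pulled inward
  if needed so it stays inside the colony). Every image carries a JSON
  ground-truth record (fraction, footprint size, seed, and a suggested
  batch threshold at background + half the single-cell amplitude).

Defaults: areal density 1500 cells/mm² (a plausible settled-drop density;
recorded in config, not a measured value), cell radius 5 um, pixel size
5 um/px. These give nuclear area coverage λ = ρπr² ≈ 0.12, deliberately
sub-confluent: the union area of randomly placed discs is
`A·(1 − e^{−λ})`, so at low λ the thresholded area of each channel stays
nearly proportional to its cell count and the area-based resistant
fraction is close to the count fraction (predicted bias ≈ 0.01 at a true
fraction of 1/3; it grows with λ, which is why confluent rendering would
break the area-fraction readout). Sub-colony geometries are insensitive to
λ because the two populations occupy essentially disjoint regions.

What the generator does **not** emulate: illumination gradients,
photobleaching, PSF blur, nucleus-size variability, cell motility or
growth between frames (images are single-timepoint snapshots), and
real-image artefacts like debris. Passing closure tests therefore
demonstrate the correctness of the measurement pipeline's geometry and
bookkeeping, not robustness to real microscopy noise.

All randomness flows from a single integer seed through
`numpy.random.default_rng` (PCG64); identical spec + seed reproduces
bit-identical images.

## Image quantification

Stitching is pure grid placement with symmetric cropping of the stated
tile overlap — no registration or blending. Segmentation is
`image > threshold` (Otsu for `"auto"`; an explicit threshold should be
held fixed across a batch), followed by optional binary closing + hole
filling (`close_radius`), removal of components under 50 px, and
largest-component selection. The closing step is a deliberate departure
from manual outline tracing: with sub-confluent nuclei the raw mask is
thousands of dots, and the colony footprint only becomes a single
component after gaps of a few nearest-neighbour spacings are closed
(radius 8 px at the default density/pixel size). For footprint *size*
measurements the `convex_hull` option replaces the mask by its convex
hull, consistent with treating the colony as a perfect disc; without it
the scalloped rim between boundary nuclei biases the equivalent diameter
low by a few pixels. The resistant area fraction
`(nuclei − marker)/nuclei` always uses the raw threshold masks of both
channels at one shared threshold, with no morphological cleanup, and is
clipped to [0, 1].

Degenerate inputs: an all-background image yields area 0 with a warning
record (not an exception); zero nuclei area makes the fraction undefined
(error); a zero initial radius makes normalisation undefined (error).

## Problem sizes

Tests and the acceptance script run at desk scale: plates of 8 doses × 3
replicates, dose grids of tens of points, and colonies of 2,000–50,000
cells on images up to ~1500² px (the 50K-cell colony). These sizes were
chosen so the full suite completes in well under a minute while every
closure tolerance is still binding.

## Known limitations

* Non-spatial dynamics: no competition for space/nutrients, no clone
  geometry effects on drug exposure; the image layer and the dynamics
  layer are linked only through parameters, not through a spatial model.
* No pharmacokinetics: dose is an instantaneous multiplicative survival,
  with no decay, scheduling within the interval, or accumulation.
* No resistance acquisition: `N_r` changes only by growth.
* The area-based resistant fraction is accurate for sub-confluent stains;
  in near-confluent scattered colonies the union-area measure
  systematically underestimates the resistant share.
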