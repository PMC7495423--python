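# Methods

This note documents the models behind `phylolegacy`, the choices made
where the design was genuinely open, and what the synthetic landscapes
do and do not establish about real data.

## Spatial frame

All stages share one metric lattice of square cells (default 50 km
edge), 0-based row-major ids with the origin at the south-west corner.
A single boolean mask marks analyzed land cells; a cell that is missing
in *any* input (e.g. a NaN climate slice) is dropped from the mask
everywhere, with counts logged. Rasters on disk are plain-text ASCII
grids (6-line header; file rows run north to south per that format,
in-memory arrays run south to north). The lattice is already metric, so
no projection step exists; real-data use would reproject to an
equal-area CRS upstream.

## Simpson phylogenetic turnover and its correction

Branch incidence: a site carries a branch iff at least one tip below it
is present; the root edge is excluded. For sites *i*, *j* with shared
carried length *A* and unique lengths *B*, *C*,
`pbeta_sim = min(B,C) / (A + min(B,C))` — symmetric, in [0, 1], zero for
nested branch sets, so richness gradients alone produce no turnover.

Each occupied cell is paired with its *k* = 24 nearest occupied
neighbors (8 and 48 are conventional alternatives); neighbors are ranked
by centroid distance, ties at rank *k* broken by cell id. Empty cells
are excluded with a warning, and asking for more neighbors than exist is
an error rather than a silent shrink.

Environmental distance: present-day climate values at the analysis
cells are z-scored, a PCA is run, and distances are Euclidean in the
retained-axis score space. With six or more variables exactly six axes
are retained by default (a cumulative-variance threshold, default
0.98, is the selectable alternative); with fewer variables all axes are
kept, which makes the distances equal to z-space distances exactly.

The correction is one global OLS of logit-transformed mean turnover on
{geo, geo², env, env²} plus intercept, fitted on the per-focal-cell
means; the residual is `pbeta_simC`. The per-cell-mean formulation was
chosen because the statistic is defined per raster cell; a pair-level
variant (regress individual neighbor pairs, average the pair residuals
per focal cell) is available behind a flag. Turnover means are clamped
to [1e-3, 1 − 1e-3] before the logit; residuals are exactly orthogonal
to the design columns (tested to a 1e-8 cosine), so pbeta_simC has mean
zero by construction.

## Climate-change velocity and stability

Velocity per variable and 1000-year step is |s/g|: *s* the two-point
slope of the cell's values across the step (units/yr), *g* the
magnitude of the central-difference gradient over the 3×3 neighborhood
(units/km), taken from the older slice of the step (the state when the
displacement began). Choices that matter:

* gradients are floored at `g_min = 1e-4` units/km so flat fields do
  not divide to infinity; on top of that, after averaging steps and
  maximizing across variables, cells above the 99.5th percentile of
  masked cells are reset to that percentile (both counts logged);
* per-step velocities are converted to absolute values *before*
  averaging (the alternative — average then absolute — would let
  cooling and warming episodes cancel);
* the natural log is used (any base is a monotone rescale), with a
  velocity floor of 1e-6 km/yr so a perfectly static climate has a
  defined log;
* the final 5×5 low-pass filter averages over masked cells only, no
  padding, because velocity is dominated by topographic gradients at
  scales finer than 50 km community data; a uniform field is a fixed
  point of the filter.

Stability: per cell and variable, variability is the standard deviation
of consecutive-slice differences (a mean-absolute-difference mode is
the flagged alternative); note that with a constant temporal trend this
measures fluctuation around the trend, not the trend itself. Stability
is 1/variability (variability floored at 1e-9, flagged), each variable's
map divided by its masked maximum, the maps multiplied, and the product
rescaled once more, so the combined map lies in [0, 1] with maximum
exactly 1.

## Niche models, spread automaton, refugia

The occurrence GLM is binomial with logit link, terms {v, v²} per
climate variable, and case weights scaling presences and absences to
equal total mass (prevalence 0.5). Term columns are standardized
internally for conditioning; this is an affine reparametrization that
leaves fits and predictions unchanged. The IRLS solver declares
convergence on relative deviance change (tolerance 1e-9, step-halving
on deviance increase) — the standard GLM criterion, and the robust one
here because presences generated by thresholding are quasi-separable:
coefficients can grow without bound while the deviance plateaus. A
ridge-stabilized fallback (penalty 1e-6 on the standardized scale,
intercept unpenalized) catches outright failures and is logged.
D² = 1 − residual deviance / null deviance under the same weights.

Hindcast suitability is the inverse-logit prediction per slice.
Candidate refugial origins are cells with LGM suitability strictly
greater than 0.5 (a cell at exactly 0.5 is excluded).

The spread automaton runs m ∈ [1, 10] iterations per slice interval,
oldest to present, on the *older* slice's suitability. Stochastic mode:
one Bernoulli event per cell per iteration with probability h² — an
occupied cell persists, an unoccupied cell with an occupied 8-neighbor
colonizes (local extinction otherwise); the accessibility map flags
cells occupied in ≥ 50% of 30 replicates, each replicate seeded from a
hash of (species, origin, m). Deterministic mode — the default and the
testable one — thresholds h² > 0.5 per interval, which makes one
iteration exactly one step of breadth-first reachability within the
habitable set (verified against an independent BFS oracle) and makes
the reached set monotone in m. The persistence rule (occupied cells
must remain habitable) is a declared choice; the behavior of the
original automaton under deteriorating suitability is not fully
specified by its description.

An origin is retained when adding its accessibility column strictly
increases D² with a positive coefficient; an accessibility column with
no variation (all or none reached) is inestimable and the origin is
rejected. The selected migration rate m\* maximizes the mean
D²-with-accessibility over retained origins (max-over-origins is the
flagged alternative; the source phrasing is ambiguous), ties going to
the slower rate. Species with no retained origin at any rate are
flagged and excluded from DistRef averaging. Per-cell DistRef is the
mean, over species present, of the Euclidean distance to that species'
nearest retained cell; RangeS the mean occupied-cell count.

## Driver attribution

The response and each driver are standardized; quadratic terms are
squares of the standardized driver, themselves standardized. DistRef
and ClimStab are never in the same model (they are strongly
anticorrelated by construction); both variants are always emitted,
along with the 4×4 driver correlation matrix. LMG importance is
computed at group level — a driver's linear+quadratic pair enters the
ordering average as a unit — by exhaustive enumeration of the 2³
subsets (exact and cheap); summing term-level shares is the flagged
alternative and agrees closely. The three unrescaled contributions sum
to the full-model R² exactly; rescaled importances sum to 1. Cells with
any missing driver (e.g. all their species lack inferred refugia) are
dropped, with counts logged.

## The synthetic landscapes

The generator produces the statistical structure the analysis assumes,
with ground truth for parameter recovery. One 20×20 lattice of 50 km
cells (any size ≥ 3×3 works; partial masks are grown as a single
8-connected region); 22 climate slices spanning 21 kyr in 1000-year
steps; two variables, annual mean temperature and annual precipitation
sum. A slice value is

    base + gradient·y + trend(region)·t + microclimate(cell) + noise(cell, t)

with the mask split into southern and northern halves by latitude.
The default scenario encodes a stylized glacial history:

* temperature falls from ~13 °C to ~−2 °C northward at the LGM
  (−0.016 °C/km) and warms by 0.02 °C/kyr in the stable south versus
  0.15 °C/kyr in the north, so the north opens to colonization late;
* niche optima evolve by Brownian motion (sd 2.5 °C per unit tree
  depth) on a Yule phylogeny around a warm-biased root (13 °C); because
  a species must have LGM habitat somewhere, the realized optima pile
  against the warm southern edge — a Mediterranean-style diversity
  ridge. Niche widths are lognormal (median 1.8 °C, log-sd 0.6), so a
  minority of broad-niche generalists can blanket the north;
* three shared southern refugial hotspots are drawn, each species
  receiving one refugial cell near each hotspot among its LGM-suitable
  cells; microclimate amplitude (persistent per-cell offsets) decays
  with distance from the hotspots (1.6 °C near, ~0.1-0.4 °C on the
  northern plains), tying topographic complexity to the refugial
  regions, as in the system being emulated;
* precipitation carries the strong regional trend (2 vs 12 mm/kyr) and
  noise contrast (4 vs 14 mm per slice), which places high
  climate-change velocity and low stability in the north;
* present-day ranges are produced by the deterministic spread operator
  itself (2 iterations per step) from the true refugia through the
  sliced Gaussian-niche suitability, intersected with present-day
  suitability — so every range is reconstructible from the stored truth,
  an invariant the tests assert. A species whose niche leaves it
  without LGM habitat or with an empty range gets a freshly drawn
  optimum and width (20 retries, then a hard error: silently dropping
  species would bias turnover).

Every output is a deterministic function of one seed.

What the scenario does *not* emulate: coastline or elevation geometry,
extinction and speciation dynamics, observation error in atlas data,
taxonomic noise, and more than two climate variables. Passing tests
therefore show the pipeline recovers the structure *this* generative
model plants — directional homogenization away from refugia, refugial
ground-truth recovery, stability–distance anticorrelation — not that
real floras behave this way.

A structural finding worth recording: on these landscapes the LMG
ranking is led by range size or velocity rather than distance to
refugia (typical shares ~0.1–0.3 DistRef, ~0.3–0.5 Vocc, ~0.4–0.6
RangeS). Wherever Simpson turnover is generated by small-ranged
species, per-cell mean range size is an almost direct readout of the
turnover-generating composition, and at desk scale (hundreds of cells,
tens of species) distance to refugia is a strictly noisier proxy of the
same gradient. The continental-scale dominance of distance to refugia
reported for real floras is not reproduced at this scale, and the
corresponding check is left failing rather than redesigned around.

## Problem sizes

Defaults used by the test suite and the acceptance script: 20×20 cells,
60 species (20 single-refugium species for recovery runs), 22 slices,
k = 24, migration rates 1–10, deterministic spread. A full scenario
runs in tens of seconds on one core; the dominant cost is the
per-origin × per-rate GLM refit, which is batched across origins.
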