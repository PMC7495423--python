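# phylolegacy

Spatial phylogenetic turnover of gridded plant assemblages and its
Quaternary climate drivers, as a tested, reusable pipeline.

Rapid post-glacial climate change is thought to have *homogenized* plant
assemblages across recolonized landscapes: sites far from glacial
refugia were reached by a phylogenetically narrow set of widespread
generalists, so neighboring communities there are more similar than
their environments predict. `phylolegacy` implements the full analysis
chain needed to test this on a gridded flora — and, because the
real atlas, paleoclimate and megaphylogeny inputs are restricted or
large, ships a first-class synthetic-landscape generator with known
refugial ground truth, so every stage can be validated end to end.

## The statistics at the core

**Corrected Simpson phylogenetic turnover (phylo-β_simC).** For a pair
of sites, phylogenetic turnover is computed on the branch lengths of a
shared dated phylogeny: with *A* the total branch length carried by both
sites and *B*, *C* the lengths unique to each,

    phylo-β_sim = min(B, C) / (A + min(B, C))

which ignores richness differences (a nested site scores 0). Each
cell's mean turnover to its *k* = 24 geographically nearest occupied
neighbors is logit-transformed and residualized, by a single OLS, on
mean geographic and environmental distance (linear + quadratic;
environmental distance is Euclidean in the space of the leading
principal components of standardized present-day climate). The residual,
phylo-β_simC, is the turnover unexplained by local distance effects: low
values mark spatial homogenization.

**Climate-change velocity (Vocc)** is the gradient-based form
`v = s / g` (km/yr): the cell-wise temporal trend per 1000-year step
divided by the local 3×3 spatial gradient, per-step absolute values
averaged from the Last Glacial Maximum (21 kyr BP) to the present,
maximized across climate variables, reset above the 99.5th percentile,
log-transformed, and smoothed with a 5×5 masked mean filter.
**Climate stability** is the inverse of the standard deviation of
consecutive-slice differences, rescaled to [0, 1] per variable and
combined multiplicatively.

**Refugia inference.** Per species, a prevalence-weighted quadratic
logistic regression of present occurrence on climate is hindcasted to
every 1000-year slice; from each LGM-suitable cell (suitability > 0.5) a
KISSMig-style 3×3 automaton (colonization/persistence from squared
suitability) simulates range expansion at 1–10 iterations per step, i.e.
21–210 iterations since the LGM. A cell is retained as potential
refugium when its binary accessibility map raises the explained deviance
D² of the occurrence model with a positive coefficient; the migration
rate whose accessibility explains occurrences best is kept. Distance to
refugia (DistRef) and mean range size (RangeS) per cell follow.

**Attribution.** A standardized regression explains phylo-β_simC from
DistRef, Vocc and RangeS (linear + quadratic each; climate stability
substitutable for DistRef), and the LMG (Shapley) decomposition of R²
assigns each driver's relative importance — computed exactly by subset
enumeration, with a variable's linear and quadratic terms entering as
one group.

## Worked example

```sh
phylolegacy init-config --outdir demo_run --seed 1 --config demo.yaml
phylolegacy all --config demo.yaml
```

This generates the standard 20×20-cell (50 km) synthetic landscape —
60 species descending from three shared southern refugial hotspots —
and runs every stage (about half a minute), printing:

```
wrote 55 artifacts (config 4b209cd2463a)
```

`demo_run/` then contains the community table, Newick tree, per-slice
climate rasters, `turnover.csv` (per-cell phylo-β_simC), `vocc.asc`,
`climstab.asc`, `refugia.csv` (per species: retained origin cells, best
migration rate, D² before/with accessibility), `drivers.csv` and
`importance.csv`. On this run the DistRef-variant driver model reaches
R² = 0.68, corrected turnover is clearly lower in the recolonized north
(mean south − north gap 1.94 on the logit scale), and climate stability
correlates negatively (r = −0.71) with distance to the inferred
refugia — the signature of a flora still carrying its glacial legacy.

Each stage is also available as a library call (`phylolegacy.turnover`,
`.climate`, `.refugia`, `.drivers`, `.synthetic`) on in-memory objects.

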