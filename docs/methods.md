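# Methods

## Scope and data model

The analysis unit is a conifer tree ring observed on a tangential strip of
fixed width (1 mm by default).  Input is one row per tracheid with: radial
and tangential lumen diameters (μm), lumen area (μm²), four single-wall
thicknesses (pith/bark tangential walls, left/right radial walls, μm), wall
area (μm²), and the cell's file/radial ordinals.  Cells are treated as
elliptical for lumen area and conductivity and as rectangular for radial
bookkeeping (ring width, wall footprint); the cell-table validator admits
both conventions via a 1e-6 relative tolerance on the elliptical bound
`LA ≤ (π/4)·Drad·Dtan`.

## Trait derivation

**Earlywood/latewood.** A cell is latewood when the Mork index
`4 × single radial wall / radial lumen diameter` reaches 1 (the classical
cut; the threshold sits at exactly 1, latewood iff ≥ 1).  A shape-based
alternative (latewood iff `Drad/Dtan < 1`) is provided.  The ring boundary
is the relative position of the first cell of each file's *terminal*
latewood run (isolated latewood-like cells mid-file do not open the
latewood zone), averaged over files; rings lacking one of the two zones
get boundary 0/1 and a degeneracy flag instead of an error.

**Conventions that the numbers depend on.**

* Single walls are averaged per axis before use; the "double wall" *t* of
  the reinforcement index is twice the averaged single wall, and `(t/b)²`
  takes whichever axis yields the smaller *t/b* before squaring.
* Percentile columns (`_01, _25, _50, _75, _99`) use linear interpolation
  between order statistics; `tb2_05` is the 5th percentile of per-cell
  `(t/b)²` (an earlywood-weighted safety summary).
* Ring means over cells are unweighted; means over an empty earlywood or
  latewood subset are reported missing (NaN), never 0, while counts and
  widths of an empty subset are genuinely 0.
* The xylem area behind cell density and `Ks` is ring width × strip width,
  because the analysis window is the 1-mm strip, not the whole ring.
* `RWD = CWA/(CWA + CA)` reads *CA* as the lumen area, making RWD the wall
  fraction of the cell footprint; if CA is meant as total cell area the
  caller can derive it from the stored columns.
* `NoCells_tang` counts radial files containing latewood cells per mm of
  strip (file-count reading of a "tangential count in the latewood");
  `NoCells_rad = CNO / NoCells_tang`, and the earlywood/latewood per-file
  counts partition it exactly.
* Basal area increment anchors the stem radius at DBH/2 at the bark of the
  outermost measured ring, so the pith-side radius of the oldest measured
  ring is DBH/2 minus the summed measured widths (bark ignored).  A lone
  ring without this anchor reports BAI as missing.

**Hydraulics.** `Dh = Σd⁵/Σd⁴` over lumen-area equivalent circle diameters.
Conductivity sums laminar flow over all conduits of the strip acting in
parallel along a 1-m tube with no pit resistance: elliptical tubes
`k = π a³ b³ / (4η (a² + b²) L)` by default (semi-axes from the measured
diameters), or area-equivalent circles `k = π r⁴ / (8ηL)` via a switch;
the two coincide exactly for circular cells.  Constants: water viscosity
η = 1.002e-9 MPa·s (20 °C), density 998.2 kg·m⁻³.  `HCUE` is reconstructed
from its units as mass-flow conductivity (`Kh` × water density) divided by
the ring's total wall area (μm²) — a conductivity return per unit of
carbon investment; the reconstruction is a package choice, flagged here
because published definitions vary.

**Catalogue size.** The catalogue expands every percentile family to five
columns, giving 74 trait columns; headline counts in the literature that
quote ~65 traits group percentile variants differently.

## Synthetic stand generator

The generator emulates a three-plot altitudinal transect (dense young
high-elevation plot; two mixed mature plots), 10 trees per plot, five
calendar years.  Heights, ages and DBH have uniform marginals over the
plot-specific ranges (spread-maximising sampling) coupled by a Gaussian
copula; the latent height–age correlation of 0.55 yields a within-plot
Pearson r of ≈ 0.5 (target band 0.4–0.7, configurable).

Each ring is built file by file as a tracheidogram: an earlywood plateau
followed by a logistic decline (width 0.03 of the profile, i.e. the
transition occupies roughly the final quarter) of the radial lumen from its
earlywood to its latewood value while walls thicken, with the logistic
centre placed so that the noise-free Mork index crosses 1 exactly at the
start of the file's latewood block.  The latewood cell count per file is
truncated-normal (mean 6, SD 1.5, minimum 3) and roughly constant, so ring
width is driven by the earlywood cell count — a lognormal tree-level
quantity (median 55, individual log-SD 0.55) spanning roughly 20–200 cells
per file across trees.  Tangential pitch fixes the file count:
`⌊1000 μm / (Dtan + 2·CWTtan)⌋`.

Fixed effects are linear on the natural scale: Dtan +0.5 μm/m and Drad
+0.3 μm/m of height (tangential > radial, so taller trees also have fewer
files), walls +0.008 μm/yr of age, latewood share +0.03 %/yr (implemented
by scaling the latewood count mean relative to a 10% baseline share).
These defaults were chosen once so that single-year stands show
height–diameter and age–wall determination in the R² ≈ 0.3–0.6 range
typical of stand-scale dendroanatomical data, with baseline anatomy
(Dtan 28 μm, earlywood Drad 32 μm, latewood Drad 8 μm, walls 2 / 4.5 μm)
in the range of mature spruce.

Random effects are Gaussian on the log scale for positive quantities,
decomposed into individual (log-SD 0.06–0.55 per parameter), year
(≤ half of individual, by construction the dominant/shared-year ordering
needed for inter-annual ordination stability) and cell components
(within-ring earlywood Drad CV 0.04 ≤ 5%).  Individual effects can be
spatially autocorrelated through a Gaussian-kernel covariance on tree
positions (range 15 m); by default only the dense high plot enables it,
so spatial signal is detectable there while the other plots stay at the
null (whose Moran-type expectation is −1/(n−1), not 0).  All randomness
derives from one master seed; each ring uses a substream keyed by
(tree index, year), so any ring is reproducible in isolation.

**What the generator does not emulate:** climate forcing and
year-as-signal (years are i.i.d. effects), pith-to-bark ontogenetic
trends, intra-annual density fluctuations, compression wood, measurement
segmentation errors, and missing rings.  Tests passing on this generator
therefore validate the algebra and the statistical machinery, not the
ecological realism of any particular dataset.

## Statistical chain

* **Best-of-three fits** compare linear, exponential (`ln y ~ x`) and
  logarithmic (`y ~ ln x`) least squares by R² *in each family's own
  fitted space*; this mirrors common practice but is not a likelihood
  comparison, and families are skipped when their transform is undefined.
* **Year-wise PCA** standardises columns (n−1 SD), decomposes by SVD,
  drops incomplete traits and (with a warning, by default) constant
  traits, and fixes signs so the largest-magnitude loading per component
  is positive.  Variance shares sum to 100 over the retained (non-null)
  components.
* **Backward selection** starts from `PC ~ height + age + plot` (plot as a
  categorical block) and drops terms by nested Gaussian LRTs
  (`n·ln(RSS_r/RSS_f)` against χ²) at α = 0.05, largest p first; an exact
  fit in both nested models counts as no evidence for the larger one.  A
  companion Type-II F table is emitted for comparison.
* **Mantel and Procrustes** permutation tests are one-tailed (greater)
  with `p = (hits + 1)/(n_perm + 1)` over 999 permutations by default.
  The Procrustes statistic is the symmetric protest form: both score
  configurations centred and scaled to unit sum of squares, rotation from
  the SVD of `YᵀX`, `m² = 1 − (Σσ)²`, `r = √(1 − m²)`; by default the
  first 2 PCs enter.  Mantel distances in trait space are Euclidean over
  the first 3 PCs (the metric is a package choice; the component counts
  are configurable).
* **Stability ranking** computes per-individual CVs across years
  (100·SD/mean, n−1), averages and ranges them per trait, and flags traits
  at mean CV > 10% and range > 20%.
* No multiple-testing correction is applied inside the pairwise trait
  scan; a Benjamini–Hochberg column is attached for the reader only.

## Validation sizes

The test suite validates the trait formulas against an independent
plain-Python per-cell oracle on 100 randomized rings at 1e-9 relative
tolerance; permutation type-I calibration uses 500 null replicates at
n = 30 with 999 permutations; effect recovery uses 100 replicate
single-year stands (30 trees each).  These sizes keep the full suite in
the minutes range on one core while holding Monte-Carlo error well below
the asserted margins.

## Known limitations

* The ROXAS header alias map is best-effort and unverified against any
  specific export version; validate renamed tables before trusting them.
* `HCUE` follows the units-based reconstruction described above.
* The backward selection uses pure nested LRTs; analyses based on Type-II
  tests per covariate can differ on unbalanced designs (the emitted
  Type-II table makes the comparison visible).
* Generator profiles are logistic by construction; analyses of curve
  *shape* on synthetic data inherit that choice, and the analysis stage
  deliberately makes no use of it.
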