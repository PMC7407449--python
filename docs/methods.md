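# Methods

`flymap` implements the computational core of a classical Drosophila
forward-genetics mapping study: placing a recessive lethal on the genetic map
from testcross counts, narrowing it cytogenetically with deficiency
complementation, localizing the molecular lesion with overlapping PCR, and
the Mendelian survival statistics used to characterise the mutant. Every
stage is backed by a seedable synthetic-experiment generator so the whole
pipeline can be exercised and calibrated without external data.

## The mapping model

### Cross design and the RF statistic

The design is a three-generation cross. The lethal is kept over a balancer
(`TM6B`, dominantly marked, homozygous lethal). F2 females carry the lethal
chromosome over a multiply-marked chromosome (`ru h th st cu sr e ca`) in
**repulsion phase**: the lethal sits on the marker-wild homolog. Meiotic
recombination in these females produces recombinant chromosomes; each scored
F3 male carries one such maternal chromosome (males do not recombine, so the
paternal contribution is inert). The male's lethal-locus state is read out by
a testcross to lethal/balancer females: if his tested chromosome carries the
lethal, the non-balancer progeny class is absent.

`infer_l_status(non_balancer, total, min_total)` encodes exactly that rule:
`l` when zero non-balancer adults emerge from a cross of at least `min_total`
(default 20) scored adults, `l+` when any emerge, `unknown` otherwise.
Unknown males are excluded from tallies (never imputed) and the exclusion
count is reported.

For each marker the chromosomes partition into parental
(marker-wild ∧ l, marker-mutant ∧ l+) and recombinant classes, and

    RF = 100 · R / (P + R)    [percent]

with an exact Clopper–Pearson confidence interval on R successes in P+R
trials (default 95%; exact rather than asymptotic because several observed R
are tiny — 3, 5, 8 out of 113). RF percent is read directly as map distance
in cM (identity map function) by default, reproducing the study's published
arithmetic; Haldane and Kosambi corrections are available via
`map_function=` but change the distant markers most and are off by default.

Displayed RF values are **truncated**, not rounded (`format_rf`): the
published tables print 7.07 for 8/113 = 7.0796 and 30.08 for 34/113 =
30.0885, which only truncation reproduces. All numeric comparisons use the
untruncated value.

### Locus placement

`place_locus(..., method="flank_subtraction")` anchors on the minimum-RF
marker (ties broken toward larger sample size and noted in the result). The
side is chosen by consistency: for each hypothesis (locus left/right of the
markers) the marker-implied positions pos(m) ∓ rf(m) are computed over the
informative set, and the side with the smaller sum of squared deviations
from their mean wins — a locus on the correct side makes the implied
positions cluster. The reported `bounds` are the [min, max] of the implied
positions over the informative marker set, by default the two smallest-RF
markers (the anchor is dropped only when its RF is exactly zero, where it
cannot resolve a side and the placement degenerates to the anchor position).
With the published refined inputs (st 1.23% @ 44.0 cM, cu 8.29% @ 50.0 cM)
this yields 41.71–42.77 cM, left of thread.

**Point bounds vs coverage.** The point interval between two implied
positions is a display convention, not a confidence interval: both endpoints
are noisy, nearly unbiased, positively correlated estimators of the same
locus position, so the interval between them brackets the truth only when
the two estimates happen to straddle it (~50% at best, and much less at
small sample sizes where RF takes coarse discrete values). `PlacementResult`
therefore also carries `ci_bounds`, the same subtraction applied to each
informative marker's exact RF confidence limits. Empirically (see the
acceptance suite) the CI interval covers a truth at 42.3 cM in ≥ 97% of
seeded replicates at the study's scale of 113 males, while the point
interval's coverage rises from ~3% at 28 males toward ~25% at 452 as RF
discreteness shrinks. Coverage statements in tests use `ci_bounds`; the
published-arithmetic reproduction uses `bounds`.

`method="least_squares"` instead minimises Σ (rf(m) − |pos(m) − x|)² over a
0.01 cM grid spanning the map ± 10 cM, with a parametric-bootstrap interval
(R ~ Binomial(n, rf) per marker, 200 resamples by default). It uses all
markers and is the better choice on synthetic data at large n (bias < 1 cM
at 1,000 males); the flank method is the faithful reproduction of the
published procedure.

## Cytogenetic machinery

Bands follow the polytene nomenclature (arm, division 1–102, letter A–F,
optional positive sub-band) with total order (division, letter, sub-band)
within an arm; a missing sub-band sorts before sub-band 1. The arm may be
inferred from the division via the standard ranges (61–80 → 3L, etc.).
Interval endpoints written without a sub-band expand to the full lettered
band (`72A` ⇒ `72A1`–`72A20`); the 20-sub-band ceiling is an assumption
(`MAX_SUBBAND`), overridable per interval, since band catalogues do not fix
a uniform count.

`solve_region` computes, on the discretized band lattice, the set of bands
contained in **every** failing deficiency and in **no** complementing one —
equivalent to per-band voting, which the tests check exhaustively on small
lattices. Contiguous runs become candidate fragments, ranked by width.
Failing deletions with an empty joint intersection raise an inconsistency
error naming a conflicting pair; a complementing stock that covers the whole
intersection is named in its own error. Real breakpoint uncertainty is out
of scope: deletions are taken at face value on the lattice.

`check_allelism` declares a gene allelic when at least one lethal allele
fails to complement and the gene's band lies inside the solved region or
within `radius_divisions` of it (default 1). The allowance is deliberate
and logged in the verdict: the motivating screen solved to 71F4–71F5 — a
gene-desert — yet the culprit gene sits at the abutting band 72A1, so a
zero-radius rule would reject the true gene. The packaged deficiency
breakpoints are synthetic stand-ins consistent with that narrative (the
real breakpoints were published only as supplementary material).

## Molecular fine mapping

Genomic intervals are 1-based and fully inclusive (`start..end`), so
`3L:15826279..15827223` has length 945 — the convention is forced by the
published 945 bp worked example. `find_lesion_interval` unions the intervals
of anomalous amplicons (failed, or amplified at a size shifted beyond a 10%
default tolerance — both regimes occur in practice, outright failure under
standard extension and a ~8.5 kb product under long-range conditions),
subtracts every base covered by an amplicon that amplified at wild-type size,
and reports the minimal interval containing what remains. Disjoint anomalous
clusters produce a multi-lesion result listing all clusters. On simulated
tilings the returned interval always contains the hidden insertion site at
zero noise, and its width is bounded by one amplicon length plus overlap.

`insertion_size` is the plain difference of product sizes (negative ⇒
deletion). `relative_abundance` averages replicate lanes per genotype/role
and reports target/control ratios and fold-changes against a reference
genotype; the ratio cancels common per-lane scale, which is the point of the
internal control. Multi-band repeat-ladder profiles are out of computational
scope and only describable as metadata.

## Survival statistics

`RatioModel` holds Mendelian class proportions at fertilization plus
per-class, per-stage conditional survival probabilities (zero encodes a
lethal class, e.g. balancer homozygotes dying as embryos). Expectations at a
stage are renormalized over surviving classes when the observed denominator
is stage-conditional — the intercross expectation of 1/3 non-Tubby : 2/3
Tubby among hatched larvae falls out of 1:2:1 with one embryonic-lethal
class. Each published table keeps its own denominator convention (the
viability table reports each stage relative to the previous one; the rescue
table reports eclosion relative to total pupae — verified by 94/442 =
21.3%), and the stage functions follow the caller's denominators rather than
imposing one.

Goodness of fit uses the Pearson chi-square for ≥3 classes and the exact
binomial for 2 (forceable via `method=`). The chi-square route is calibrated
— type-I error within Monte-Carlo error of 5% over 1,000 null simulations at
n = 500 eggs — while the exact route is conservative by construction, which
is why the calibration check runs on a 3-class design. `arcsine_sqrt` is the
standard variance-stabilising asin(√p) used before parametric testing of
proportions; fertility assays get exact binomial CIs.

One published expectation does not follow from any model stated with it: the
egg-hatch expectation of 66.7% matches neither 3/4 (one embryonic-lethal
class out of 1:2:1) nor the 50% printed for the larval classes. The larval
counts themselves (468:473) sit on 1:1 — consistent with deliberately
transferring similar numbers of each class — and reject 1/3:2/3 outright.
The package exposes `RatioModel` so the analyst states the design rather
than having one imposed; the viability driver prints both comparisons.

## The synthetic generator

The generator reproduces the statistical structure the analysis assumes:

* **Crossovers** — default `haldane`: no interference, so recombination
  events in disjoint intervals are independent and adjacent-interval
  indicators are Bernoulli with the Haldane probability (1 − e^(−2d/100))/2;
  at the marker loci this is exactly the Poisson crossover process.
  `map_function="identity"` (capped at 50%) and Kosambi are available, as
  are `fixed_count` (k uniform crossovers) and `gamma_interference`
  (stationary gamma renewal, shape ν > 1 ⇒ positive interference) models.
* **Males** transmit their maternal chromosome unchanged (the Drosophila
  no-male-recombination rule; the testcross readout never involves male
  meiosis).
* **Testcross readout** — progeny classes from a recombinant/tester male ×
  lethal/balancer female cross; the informative (non-balancer) class is
  Binomial(n, 1/4) and dies when the tested chromosome carries the lethal.
  With the default 40 progeny per male and `min_total` 20, miscalls are
  ~1e-5 per male; `misclassification_rate` (default 0 — a nonzero default
  would silently inflate RF) adds recording error on top.
* **Deficiency panels** — deletion spans geometric with mean 40 lattice
  bands, uniform placement; outcome is deterministic containment of the true
  band, flipped with `noise_rate`; one covering deletion is appended if a
  random panel happens to contain no hit (a screen is continued until one).
* **Tiling panels** — fixed-length amplicons (default 500 bp, 100 bp
  overlap) stepped across the gene; the insertion adds its size to spanning
  amplicons, which fail outright above the long-range ceiling (default 3 kb).
* **Stage survival** — multinomial classes at fertilization, then binomial
  thinning per stage, giving non-increasing per-class counts by construction.

Defaults mirror the study conditions: 113 scored males, the standard
chromosome-3 marker positions (ru 0.0, h 26.5, th 43.2, st 44.0, cu 50.0,
sr 62.0, e 70.7, ca 100.7 — only thread's 43.2/72D1 is fixed by the study
itself; the rest are the standard map and user-overridable via a TSV), and a
true locus at 42.3 cM (the midpoint of the published interval) in the
recovery analyses. Simulation sizes in tests — 10,000 gametes for map-function
calibration, 200 replicates for coverage, 1,000 for type-I calibration —
are the package's chosen desk-scale settings.

What the generator does **not** emulate: viability differences among marker
classes, scoring errors on visible phenotypes (the recombinant haplotype is
assumed fully observable, although a real tester chromosome uncovers only
some recessives), crossover-count heterogeneity between females, segregation
distortion, deficiency breakpoint uncertainty, and PCR artefacts other than
the clean fail/size-shift dichotomy. Passing calibration tests therefore
demonstrates internal statistical correctness of the estimators under the
stated model, not robustness to those real-data complications.

## Numerical and degenerate-input choices

* Clopper–Pearson limits come from the beta-quantile identity; endpoints at
  R = 0 (lower limit 0) and R = n (upper limit 1) are exact.
* `estimate_rf` refuses P + R = 0; `classify_pair` reports (not drops
  silently) unknown-state exclusions.
* Flank-subtraction anchor ties break toward larger n and are recorded in
  the result note; a zero-RF anchor short-circuits to a degenerate placement
  at the anchor with CI-derived bounds.
* The least-squares grid is 0.01 cM; the test oracle re-minimises at 0.001 cM
  and agrees to within one coarse grid step.
* Band sub-band expansion uses `max_subband` consistently between interval
  construction and lattice enumeration; mixing values is the caller's error.
* All generators take explicit integer seeds; there is no module-level RNG.

## Known limitations

* The identity RF→cM convention double-counts nothing for near markers but
  compresses distances for far ones; placements driven by markers > ~15 cM
  away should use the map-function corrections.
* The published tiling span and the published candidate region are mutually
  inconsistent in the source tables (the stated 28-pair tiling interval does
  not contain the candidate region); the package makes no attempt to
  reconcile the two and all tiling fixtures are self-consistent synthetic
  constructions at the published coordinates.
* Placement assumes a single locus; two linked lethals would bias every RF
  and are not modelled.
* The complementation solver treats outcomes as binary; partial
  complementation, second-site non-complementation and dominant modifiers
  are out of scope.
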