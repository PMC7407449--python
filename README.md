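# flymap

Classical *Drosophila melanogaster* forward-genetics mapping, as a tested
Python library with narrative analysis drivers. Given the count tables a
mapping study actually produces — scored testcross males, deficiency
complementation calls, tiling-PCR outcomes, stage-survival tallies — `flymap`
computes where a recessive lethal sits on the genetic map, which cytogenetic
bands can harbour it, where the molecular lesion lies, and whether the
survival data fit a Mendelian model with lethal classes. A seedable
synthetic-experiment generator reproduces the full study design so every
stage can be exercised and calibrated end to end.

It is written for geneticists analysing two-point mapping crosses and
deficiency screens, and for anyone who wants the arithmetic of a classical
mapping study to be reproducible and testable.

## The statistics at the core

For each visible marker, scored chromosomes split into parental (marker-wild
∧ *l*, marker-mutant ∧ *l⁺*; repulsion phase) and recombinant classes, and
the recombination fraction is

    RF = 100 · R / (P + R)   [%]  ≈ map distance in cM,

with an exact Clopper–Pearson CI on R of P+R. The locus is placed by flank
subtraction: anchor on the minimum-RF marker, pick the side on which the
marker-implied positions pos(m) ∓ rf(m) cluster, and report their [min, max]
over the informative markers (plus a CI-expanded interval for coverage; see
`docs/methods.md`). Deficiency mapping intersects failing deletions and
subtracts complementing ones on the polytene band lattice; tiling PCR unions
anomalous amplicons and subtracts bases proven intact; survival tables are
tested against `RatioModel` expectations (multinomial classes × per-stage
survival, lethal classes allowed) by exact binomial or chi-square tests.

## Worked example

Placing the lethal from the study's refined two-point counts:

```python
from flymap import PairCounts, RFEstimate, estimate_rf, pool_counts, place_locus
from flymap.core import rucuca_map

# replicate testcross counts for hairy (parental, recombinant)
pooled = pool_counts([PairCounts("h", 89, 18),
                      PairCounts("h", 185, 40),
                      PairCounts("h", 96, 22)])
print(pooled.parental, pooled.recombinant)   # 370 80
print(round(estimate_rf(pooled).rf, 2))      # 17.78

# refined RFs to scarlet (44.0 cM) and curled (50.0 cM)
ests = {m: RFEstimate(m, rf, rf, rf, n)
        for m, rf, n in [("st", 1.23, 982), ("cu", 8.29, 1204)]}
res = place_locus(ests, rucuca_map())
print(res.side, res.anchor)                  # left st
print([round(b, 2) for b in res.bounds])     # [41.71, 42.77]
```

The pooled hairy counts give RF 17.78%; the refined scarlet/curled RFs place
the lethal left of thread between 41.71 and 42.77 cM — i.e. each informative
marker's map position minus its RF, with the side chosen by consistency of
the two implied positions.

The numbered drivers under `analysis/` run the full story and write their
tables to `results/`:

```
python analysis/01_simulate_cross.py     # synthetic 113-male cross, truth at 42.3 cM
python analysis/02_linkage_mapping.py    # RF table, pooling, placement 41.71–42.77 cM
python analysis/03_complementation.py    # deficiency solver -> 71F4–71F5, DCP2 allelic
python analysis/04_fine_mapping.py       # lesion at 3L:15826279..15827223 (945 bp), sizing
python analysis/05_viability.py          # survival/fertility/rescue proportions and fits
```

There is also a thin CLI (`flymap simulate|map-rf|place|complementation|
tiling|viability|report`) over the same library functions, reading the TSV
formats documented in `flymap.io`.

## Layout

```
src/flymap/        core.py (markers, bands, intervals)  linkage.py (RF, placement)
                   complementation.py  molecular.py  viability.py
                   simulate.py (synthetic experiments)  datasets.py (published tables)
                   io.py  pipeline.py  cli.py
analysis/          numbered narrative drivers (write results/)
tests/             pytest suite incl. calibration/acceptance checks
docs/methods.md    model assumptions, parameter choices, limitations
```
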