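"""Published count tables and coordinates used by the worked examples.

These are the printed inputs of the l(3)tb → DCP2 mapping study: the scored
testcross males (marker haplotype + lethal-locus status), the per-marker
parental/recombinant tallies, the replicate refinement counts, the deficiency
and allele complementation calls, the tiling-PCR coordinates, and the
stage-survival / fertility / rescue counts.

The deficiency breakpoints are synthetic stand-ins (the published breakpoints
live in supplementary material): they are constructed to be consistent with
the published narrative — four failing deficiencies whose intersection is
71F4–71F5, with DCP2 at the abutting band 72A1.
"""

from __future__ import annotations

import pandas as pd

from .core import GenomicInterval

MARKER_ORDER = ["ru", "h", "th", "st", "cu", "sr", "e", "ca"]

# ---------------------------------------------------------------------------
# Scored-male genotype classes: (mutant-marker flags in MARKER_ORDER, n_l, n_l+)
# 113 males total.  Row 10 and row 29 are mixed-status classes.
# ---------------------------------------------------------------------------
SCORED_MALE_CLASSES: list[tuple[tuple[int, ...], int, int]] = [
    ((1, 1, 1, 0, 0, 0, 0, 0), 0, 1),
    ((1, 1, 1, 1, 0, 0, 0, 0), 0, 1),
    ((1, 1, 1, 1, 1, 0, 0, 0), 0, 1),
    ((1, 1, 1, 1, 1, 1, 0, 0), 0, 1),
    ((1, 1, 1, 1, 1, 1, 1, 0), 0, 3),
    ((1, 1, 1, 1, 1, 1, 1, 1), 0, 6),
    ((0, 1, 1, 1, 1, 1, 1, 1), 0, 6),
    ((0, 0, 1, 1, 1, 1, 1, 1), 0, 6),
    ((0, 0, 0, 1, 1, 1, 1, 1), 1, 0),
    ((0, 0, 0, 0, 1, 1, 1, 1), 1, 1),
    ((0, 0, 0, 0, 0, 1, 1, 1), 2, 0),
    ((0, 0, 0, 0, 0, 0, 1, 1), 4, 0),
    ((0, 0, 0, 0, 0, 0, 0, 1), 6, 0),
    ((0, 0, 0, 0, 0, 0, 0, 0), 26, 0),
    ((1, 1, 0, 0, 0, 0, 0, 0), 6, 0),
    ((1, 0, 0, 0, 0, 0, 0, 0), 6, 0),
    ((1, 0, 0, 0, 0, 0, 0, 1), 3, 0),
    ((1, 0, 0, 0, 0, 0, 1, 1), 1, 0),
    ((1, 1, 0, 0, 0, 0, 0, 1), 7, 0),
    ((1, 1, 0, 0, 0, 1, 1, 1), 5, 0),
    ((1, 0, 0, 0, 0, 1, 1, 1), 3, 0),
    ((1, 1, 0, 0, 1, 1, 1, 1), 1, 0),
    ((1, 1, 1, 1, 1, 0, 1, 1), 0, 1),
    ((0, 0, 1, 1, 1, 1, 0, 1), 0, 1),
    ((0, 0, 1, 1, 1, 1, 1, 0), 0, 3),
    ((0, 0, 1, 1, 0, 0, 0, 0), 0, 1),
    ((0, 0, 0, 0, 0, 1, 1, 0), 0, 1),
    ((0, 1, 0, 0, 0, 0, 0, 0), 0, 1),
    ((0, 1, 1, 1, 1, 1, 1, 0), 1, 4),
    ((0, 1, 1, 1, 1, 1, 0, 0), 0, 1),
    ((0, 1, 1, 1, 1, 0, 0, 0), 0, 1),
]


def scored_males() -> pd.DataFrame:
    """Expand the genotype classes into one row per scored male.

    Columns: one per marker (``mut``/``wt``) plus ``locus_state`` (``l``/``l+``).
    """
    rows = []
    for flags, n_l, n_lplus in SCORED_MALE_CLASSES:
        alleles = {m: ("mut" if f else "wt") for m, f in zip(MARKER_ORDER, flags)}
        rows.extend([{**alleles, "locus_state": "l"}] * n_l)
        rows.extend([{**alleles, "locus_state": "l+"}] * n_lplus)
    return pd.DataFrame(rows, columns=MARKER_ORDER + ["locus_state"])


# marker -> (parental, recombinant) tallies over the 113 scored males,
# with the RF values as printed (truncated).  The ca parental subtotal is
# printed as 74, which contradicts both the 113 scored males and the printed
# RF (43.3 = 100*49/113); 64 is the value consistent with both and is used here.
PAIR_COUNTS: dict[str, tuple[int, int]] = {
    "ru": (62, 51),
    "h": (79, 34),
    "th": (110, 3),
    "st": (108, 5),
    "cu": (105, 8),
    "sr": (94, 19),
    "e": (86, 27),
    "ca": (64, 49),
}

PRINTED_RF: dict[str, float] = {
    "ru": 45.13,
    "h": 30.08,
    "th": 2.65,
    "st": 4.42,
    "cu": 7.07,
    "sr": 16.8,
    "e": 23.89,
    "ca": 43.3,
}

# replicate refinement counts: marker -> [(parental, recombinant), ...]
REPLICATE_COUNTS: dict[str, list[tuple[int, int]]] = {
    "h": [(89, 18), (185, 40), (96, 22)],
    "st": [(252, 2), (480, 6), (238, 4)],
    "cu": [(269, 22), (552, 50), (283, 28)],
}

# refined RF values as printed in the replicate table
REFINED_RF: dict[str, float] = {"h": 17.78, "st": 1.23, "cu": 8.29}


def pair_counts_frame() -> pd.DataFrame:
    rows = [
        {"marker": m, "parental": p, "recombinant": r}
        for m, (p, r) in PAIR_COUNTS.items()
    ]
    return pd.DataFrame(rows)


def replicate_counts_frame() -> pd.DataFrame:
    rows = [
        {"marker": m, "parental": p, "recombinant": r, "replicate": i + 1}
        for m, reps in REPLICATE_COUNTS.items()
        for i, (p, r) in enumerate(reps)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# complementation screen (breakpoints are synthetic stand-ins, see module doc)
# ---------------------------------------------------------------------------
DEFICIENCY_PANEL: list[tuple[str, str, str]] = [
    # (stock, deleted interval, outcome)
    ("Df(3L)BSC774", "3L:71E1-72A2", "fails"),
    ("Df(3L)BSC575", "3L:71F1-72A1", "fails"),
    ("Df(3L)BSC845", "3L:71D1-71F5", "fails"),
    ("Df(3L)RM95", "3L:71F4-72B1", "fails"),
    ("Df(3L)ED4543", "3L:71A1-71F3", "complements"),
    ("Df(3L)ED4606", "3L:72A2-72D5", "complements"),
    ("Df(3L)BSC117", "3L:70C1-71C3", "complements"),
]

ALLELE_TESTS: list[tuple[str, str, str]] = [
    # (gene, allele, outcome)
    ("DCP2", "P{GT1}DCP2[BG01766]", "fails"),
    ("DCP2", "PBac{RB}DCP2[e00034]", "fails"),
    ("Rpl36A", "Rpl36A[l1]", "complements"),
]

GENE_BANDS: dict[str, str] = {"DCP2": "3L:72A1", "Rpl36A": "3L:71F2"}


# ---------------------------------------------------------------------------
# fine-mapping coordinates (wild-type genome)
# ---------------------------------------------------------------------------
CANDIDATE_REGION = GenomicInterval("3L", 15826279, 15827223)  # 945 bp
FULL_GENE_AMPLICON = GenomicInterval("3L", 15811576, 15820204)  # 8629 bp
CNV_AMPLICON = GenomicInterval("3L", 15826497, 15826652)  # 156 bp target
CNV_CONTROL_BP = 153  # internal control (Dsor) amplicon size
MUTANT_CANDIDATE_SIZE = 8500  # ~8.5 kb long-range product over the lesion
MUTANT_FULL_GENE_SIZE = 17000  # ~17 kb full-gene product in the mutant


# ---------------------------------------------------------------------------
# stage survival / fertility / rescue counts
# ---------------------------------------------------------------------------

# balancer intercross viability: l/TM6B x l/TM6B at 23 °C
INTERCROSS_SURVIVAL = {
    "eggs_total": 1500,
    "eggs_hatched": 972,
    "non_tubby": {"larvae": 468, "pupae": 313, "eclosed": 0},
    "tubby": {"larvae": 473, "pupae": 468, "eclosed": 465},
}

# trans-heterozygote fertility: (fertile pairs, total pair matings)
FERTILITY = {"male": (28, 70), "female": (18, 83)}

# rescue crosses: ubiquitous driver over-expression in the mutant background
RESCUE_CROSSES = {
    "Act5C-GAL4": {
        "eggs": 1050,
        "unfertilized": 68,
        "pupae": 442,
        "eclosed": {"curly": 94, "non_curly": 61},
    },
    "Tub-GAL4": {
        "eggs": 1245,
        "unfertilized": 86,
        "pupae": 449,
        "eclosed": {"curly": 77, "non_curly": 89},
    },
}
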