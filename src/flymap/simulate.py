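"""Seedable generators for every input the mapping pipeline consumes.

The generators emulate the study design end to end: female meiosis over a
multiply-marked chromosome held in repulsion with the lethal (crossover
models: Haldane/Poisson by default, optional chiasma interference), the
no-male-recombination rule of Drosophila, per-male testcross determination of
lethal-locus status against a balancer, deficiency panels with breakpoints
drawn on a cytogenetic band lattice around a hidden locus, tiling-PCR panels
over a gene harbouring a hidden insertion, and multinomial-then-binomial
stage-survival tables.

All randomness flows from explicit integer seeds; identical (spec, seed)
pairs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CytoBand,
    CytoInterval,
    GenomicInterval,
    Haplotype,
    MarkerMap,
    band_lattice,
)
from .complementation import Deficiency
from .molecular import Amplicon
from .linkage import infer_l_status

__all__ = [
    "CrossoverModel",
    "ExperimentSpec",
    "DeficiencyPanelSpec",
    "TilingSpec",
    "simulate_gametes",
    "simulate_mapping_experiment",
    "simulate_deficiency_panel",
    "simulate_tiling_pcr",
    "simulate_stage_survival",
]


def _map_probability(d_cm: np.ndarray, map_function: str) -> np.ndarray:
    """Per-interval recombination probability for a map distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if map_function == "identity":
        return np.minimum(d / 100.0, 0.5)
    if map_function == "haldane":
        return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0
    if map_function == "kosambi":
        return np.tanh(2.0 * d / 100.0) / 2.0
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass(frozen=True)
class CrossoverModel:
    """Meiotic crossover process along one chromosome.

    ``haldane``            — no interference: recombination events in disjoint
                             intervals are independent, so adjacent-interval
                             indicators are Bernoulli with probability given by
                             ``map_function`` (``haldane`` reproduces the
                             Poisson crossover process exactly at the marker
                             loci; ``identity`` caps at 50%).
    ``fixed_count``        — exactly ``count`` crossovers placed uniformly.
    ``gamma_interference`` — stationary gamma renewal process with shape
                             ``shape`` (>1 ⇒ positive interference) and mean
                             inter-crossover distance 100 cM.
    """

    kind: str = "haldane"
    map_function: str = "haldane"
    count: int = 1
    shape: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("haldane", "fixed_count", "gamma_interference"):
            raise ValueError(f"unknown crossover model {self.kind!r}")
        if self.kind == "fixed_count" and self.count < 0:
            raise ValueError("crossover count must be non-negative")
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")


def _origin_matrix(
    positions: np.ndarray, model: CrossoverModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n × m matrix of parental origins (0/1) at each position."""
    m = len(positions)
    start = rng.integers(0, 2, size=n)
    if m == 1:
        return start[:, None]
    gaps = np.diff(positions)
    if model.kind == "haldane":
        rec = rng.random((n, m - 1)) < _map_probability(gaps, model.map_function)
    else:
        span = positions[-1] - positions[0]
        rec = np.zeros((n, m - 1), dtype=bool)
        for i in range(n):
            if model.kind == "fixed_count":
                points = positions[0] + rng.random(model.count) * span
            else:  # gamma renewal, stationary start
                scale = 100.0 / model.shape
                points = []
                # stationary delay: first event from the equilibrium distribution
                x = positions[0] + scale * rng.gamma(model.shape, 1.0) * rng.random()
                while x <= positions[-1]:
                    points.append(x)
                    x += rng.gamma(model.shape, scale)
                points = np.array(points)
            if len(points):
                counts, _ = np.histogram(points, bins=positions)
                rec[i] = counts % 2 == 1
    parity = np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(rec, axis=1) % 2], axis=1
    )
    return (start[:, None] + parity) % 2


def simulate_gametes(
    marker_map: MarkerMap,
    model: CrossoverModel,
    n: int,
    seed: int,
    locus_cm: float | None = None,
) -> list[Haplotype]:
    """Simulate ``n`` female gametes over the marker map in repulsion phase.

    Parental chromosome 0 carries every marker mutation and the wild-type
    lethal locus (l+); chromosome 1 is marker-wild and carries the lethal.
    If ``locus_cm`` is given, the lethal locus is threaded into the map and
    each haplotype's ``locus_state`` records the transmitted allele.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    positions = list(marker_map.positions)
    locus_idx = None
    if locus_cm is not None:
        positions = sorted(positions + [locus_cm])
        locus_idx = positions.index(locus_cm)
    rng = np.random.default_rng(seed)
    origins = _origin_matrix(np.asarray(positions, dtype=float), model, n, rng)

    marker_cols = [i for i in range(len(positions)) if i != locus_idx]
    out = []
    for row in origins:
        alleles = tuple("mut" if row[i] == 0 else "wt" for i in marker_cols)
        state = "unknown"
        if locus_idx is not None:
            state = "l" if row[locus_idx] == 1 else "l+"
        out.append(Haplotype(alleles, state))
    return out


@dataclass(frozen=True)
class ExperimentSpec:
    """Design of one synthetic mapping experiment at study scale."""

    marker_map: MarkerMap
    true_locus_cm: float
    n_males: int = 113
    n_testcross_progeny: int = 40
    min_total: int = 20
    misclassification_rate: float = 0.0
    model: CrossoverModel = field(default_factory=CrossoverModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.misclassification_rate < 0.5):
            raise ValueError("misclassification rate must be in [0, 0.5)")
        if self.n_males <= 0 or self.n_testcross_progeny <= 0:
            raise ValueError("counts must be positive")
        lo = 0.0
        hi = self.marker_map.markers[-1].cm + 10.0
        if not (lo <= self.true_locus_cm <= hi):
            raise ValueError(f"true locus must lie in [{lo}, {hi}] cM")


def simulate_mapping_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Scored-male table: marker haplotypes + testcross-inferred locus state.

    Each male inherits one recombinant maternal chromosome (no recombination
    in males); his lethal-locus state is determined by a testcross against
    mutation/balancer females: a chromosome carrying the lethal yields no
    surviving non-balancer progeny, one carrying l+ yields them at 1/4 of
    testcross progeny.
    """
    gametes = simulate_gametes(
        spec.marker_map, spec.model, spec.n_males, spec.seed, spec.true_locus_cm
    )
    rng = np.random.default_rng(spec.seed + 1)
    names = spec.marker_map.names
    rows = []
    for g in gametes:
        carries_l = g.locus_state == "l"
        informative = rng.binomial(spec.n_testcross_progeny, 0.25)
        if carries_l:
            non_balancer = 0
            total = spec.n_testcross_progeny - informative  # the l/l class dies
        else:
            non_balancer = informative
            total = spec.n_testcross_progeny
        state = infer_l_status(non_balancer, total, spec.min_total)
        if state != "unknown" and rng.random() < spec.misclassification_rate:
            state = "l+" if state == "l" else "l"
        rows.append(
            {**dict(zip(names, g.alleles)), "locus_state": state, "locus_true": g.locus_state}
        )
    return pd.DataFrame(rows, columns=names + ["locus_state", "locus_true"])


@dataclass(frozen=True)
class DeficiencyPanelSpec:
    """Design of a synthetic deficiency complementation panel."""

    true_locus_band: CytoBand
    n_deficiencies: int = 30
    div_lo: int = 61
    div_hi: int = 80
    max_subband: int = 6
    mean_span_bands: float = 40.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate <= 0.2):
            raise ValueError("noise rate must be in [0, 0.2]")
        if not (self.div_lo <= self.true_locus_band.division <= self.div_hi):
            raise ValueError("lattice must contain the true locus band")


def simulate_deficiency_panel(spec: DeficiencyPanelSpec) -> list[Deficiency]:
    """Random deletions on the band lattice; fails ⟺ deletion covers the locus.

    Each outcome is flipped with probability ``noise_rate``.  At least one
    genuinely failing deficiency is guaranteed by forcing the last deletion to
    cover the locus, mirroring a screen continued until a hit is found.
    """
    lattice = band_lattice(
        spec.true_locus_band.arm, spec.div_lo, spec.div_hi, spec.max_subband
    )
    index = {b: i for i, b in enumerate(lattice)}
    locus = spec.true_locus_band
    if locus.subband is None:
        locus = CytoBand(locus.arm, locus.division, locus.letter, 1)
    locus_i = index[locus]
    rng = np.random.default_rng(spec.seed)

    panel = []
    for k in range(spec.n_deficiencies):
        span = max(1, int(rng.geometric(1.0 / spec.mean_span_bands)))
        start_i = int(rng.integers(0, len(lattice)))
        end_i = min(start_i + span - 1, len(lattice) - 1)
        interval = CytoInterval(lattice[start_i], lattice[end_i], spec.max_subband)
        covers = start_i <= locus_i <= end_i
        outcome = "fails" if covers else "complements"
        if rng.random() < spec.noise_rate:
            outcome = "complements" if outcome == "fails" else "fails"
        panel.append(Deficiency(f"Df(sim){k + 1}", interval, outcome))

    if not any(d.outcome == "fails" for d in panel):
        # guarantee a hit: one deletion centred on the locus
        half = max(1, int(spec.mean_span_bands // 4))
        lo = max(0, locus_i - half)
        hi = min(len(lattice) - 1, locus_i + half)
        panel.append(
            Deficiency(
                f"Df(sim){len(panel) + 1}",
                CytoInterval(lattice[lo], lattice[hi], spec.max_subband),
                "fails",
            )
        )
    return panel


@dataclass(frozen=True)
class TilingSpec:
    """Design of a synthetic overlapping-PCR screen over one gene."""

    gene_interval: GenomicInterval
    amplicon_length: int = 500
    overlap: int = 100
    insertion_site: int = 0
    insertion_size: int = 0
    max_amplifiable: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insertion_size and not self.gene_interval.contains_point(self.insertion_site):
            raise ValueError("insertion site must lie inside the gene interval")
        if self.overlap >= self.amplicon_length:
            raise ValueError("overlap must be smaller than the amplicon length")


def simulate_tiling_pcr(spec: TilingSpec) -> list[Amplicon]:
    """Tile the gene with overlapping amplicons and report PCR outcomes.

    An amplicon spanning the insertion site amplifies at wild-type size plus
    the insertion size, or fails outright when that exceeds the long-range
    ceiling ``max_amplifiable``; all other amplicons report wild-type size.
    """
    g = spec.gene_interval
    step = spec.amplicon_length - spec.overlap
    amplicons = []
    start = g.start
    i = 0
    while True:
        end = min(start + spec.amplicon_length - 1, g.end)
        if amplicons and end <= amplicons[-1][2]:
            break
        i += 1
        amplicons.append((f"P{i:02d}", start, end))
        if end >= g.end:
            break
        start += step

    out = []
    for name, s, e in amplicons:
        interval = GenomicInterval(g.contig, s, e)
        wt_size = interval.length
        hit = spec.insertion_size > 0 and s <= spec.insertion_site <= e
        if not hit:
            out.append(Amplicon(name, interval, "amplified", wt_size))
        else:
            size = wt_size + spec.insertion_size
            if size > spec.max_amplifiable:
                out.append(Amplicon(name, interval, "failed", None))
            else:
                out.append(Amplicon(name, interval, "amplified", size))
    return out


def simulate_stage_survival(
    class_proportions: dict[str, float],
    stage_survival_probs: dict[str, list[float]],
    n_eggs: int,
    seed: int,
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Multinomial genotype classes at fertilization, binomial thinning per stage.

    Returns a class × stage count table whose first column is the class count
    among ``n_eggs`` and whose subsequent columns are survivors of each stage.
    """
    classes = list(class_proportions)
    props = np.array([class_proportions[c] for c in classes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    n_stages = {len(v) for v in stage_survival_probs.values()}
    if len(n_stages) != 1:
        raise ValueError("all classes need the same number of stages")
    k = n_stages.pop()
    if stages is None:
        stages = [f"stage{j + 1}" for j in range(k)]
    if len(stages) != k:
        raise ValueError("stage names must match survival-prob length")
    for c in classes:
        probs = stage_survival_probs[c]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("survival probabilities must be in [0, 1]")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_eggs, props)
    table = {"fertilized": counts}
    current = counts.copy()
    for j, stage in enumerate(stages):
        nxt = np.array(
            [rng.binomial(current[i], stage_survival_probs[c][j]) for i, c in enumerate(classes)]
        )
        table[stage] = nxt
        current = nxt
    return pd.DataFrame(table, index=pd.Index(classes, name="class"))
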