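"""Deficiency-panel interval solving and allele complementation verdicts.

A recessive lethal uncovered by a deletion fails to complement it, so the
locus must lie inside every failing deficiency and outside every
complementing one.  The solver works on the discretized cytogenetic band
lattice: candidate bands are those contained in the intersection of all
failing deletions and in no complementing deletion.  If exclusion splits the
candidate set, all contiguous fragments are returned ranked by width.

Allelism of a candidate gene is declared when at least one of its lethal
alleles fails to complement and the gene's band is consistent with the solved
region.  Consistency allows an adjacency radius (in divisions, default 1):
published deficiency breakpoints are coarse enough that a gene in the
abutting division can still be the culprit — the motivating screen solved to
71F4–71F5 yet the gene proved to sit at 72A1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CytoBand, CytoInterval, MapError, band_lattice

__all__ = [
    "AlleleTest",
    "CandidateRegion",
    "Deficiency",
    "InconsistentPanelError",
    "check_allelism",
    "solve_region",
]


@dataclass(frozen=True)
class Deficiency:
    """One deletion stock with its complementation outcome against the mutant."""

    id: str
    deleted: CytoInterval
    outcome: str  # "fails" | "complements"

    def __post_init__(self) -> None:
        if self.outcome not in ("fails", "complements"):
            raise ValueError(f"outcome must be fails/complements, got {self.outcome!r}")


@dataclass(frozen=True)
class AlleleTest:
    """Complementation outcome of one lethal allele of a candidate gene."""

    gene: str
    allele: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in ("fails", "complements"):
            raise ValueError(f"outcome must be fails/complements, got {self.outcome!r}")


@dataclass(frozen=True)
class CandidateRegion:
    """Solved candidate interval with its supporting/excluding evidence."""

    interval: CytoInterval
    supporting: tuple[str, ...]
    excluding: tuple[str, ...]
    fragments: tuple[CytoInterval, ...] = ()


class InconsistentPanelError(MapError):
    """No band satisfies every complementation outcome in the panel."""


def _lattice_for(panel: list[Deficiency], max_subband: int) -> list[CytoBand]:
    arm = panel[0].deleted.arm
    div_lo = min(d.deleted.start.division for d in panel)
    div_hi = max(d.deleted.end.division for d in panel)
    return band_lattice(arm, div_lo, div_hi, max_subband)


def solve_region(panel: list[Deficiency], max_subband: int | None = None) -> CandidateRegion:
    """Solve the candidate interval from a deficiency complementation panel.

    The candidate set is the intersection of all failing deletions minus the
    union of complementing deletions, computed band-by-band on the lattice.
    """
    failing = [d for d in panel if d.outcome == "fails"]
    complementing = [d for d in panel if d.outcome == "complements"]
    if not failing:
        raise MapError("panel has no failing deficiency")
    arms = {d.deleted.arm for d in panel}
    if len(arms) > 1:
        raise MapError(f"panel spans multiple arms: {sorted(arms)}")
    if max_subband is None:
        max_subband = panel[0].deleted.max_subband

    lattice = _lattice_for(panel, max_subband)
    in_all_failing = [all(d.deleted.contains(b) for d in failing) for b in lattice]
    if not any(in_all_failing):
        # name a conflicting pair: the first failing pair with empty overlap
        for i, a in enumerate(failing):
            for b in failing[i + 1 :]:
                if not a.deleted.overlaps(b.deleted):
                    raise InconsistentPanelError(
                        f"failing deficiencies {a.id} and {b.id} do not overlap"
                    )
        raise InconsistentPanelError(
            "failing deficiencies have empty joint intersection: "
            + ", ".join(d.id for d in failing)
        )

    keep = [
        ok and not any(c.deleted.contains(b) for c in complementing)
        for ok, b in zip(in_all_failing, lattice)
    ]
    if not any(keep):
        # every surviving band was removed by some complementing stock
        core = [b for ok, b in zip(in_all_failing, lattice) if ok]
        culprits = sorted(
            {c.id for c in complementing if any(c.deleted.contains(b) for b in core)}
        )
        raise InconsistentPanelError(
            f"complementing stock(s) {', '.join(culprits)} cover the entire "
            "failing intersection"
        )

    # contiguous runs of kept bands -> fragments, widest first
    fragments = []
    run_start = None
    for i, ok in enumerate(keep + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            fragments.append((run_start, i - 1))
            run_start = None
    intervals = tuple(
        CytoInterval(lattice[a], lattice[b], max_subband)
        for a, b in sorted(fragments, key=lambda ab: ab[0] - ab[1])
    )
    return CandidateRegion(
        interval=intervals[0],
        supporting=tuple(d.id for d in failing),
        excluding=tuple(c.id for c in complementing),
        fragments=intervals,
    )


def _division_distance(band: CytoBand, region: CytoInterval) -> int:
    if region.contains(band):
        return 0
    if band.arm != region.arm:
        raise MapError(f"gene band {band} not on arm {region.arm}")
    if band.division < region.start.division:
        return region.start.division - band.division
    if band.division > region.end.division:
        return band.division - region.end.division
    return 0  # same division as the region but outside it letter/sub-band-wise


def check_allelism(
    region: CandidateRegion,
    tests: list[AlleleTest],
    annotation: dict[str, CytoBand],
    radius_divisions: int = 1,
) -> dict[str, dict]:
    """Per-gene allelism verdicts from lethal-allele complementation tests.

    A gene is allelic when ≥1 lethal allele fails to complement and its band
    lies inside the region or within ``radius_divisions`` divisions of it.
    """
    genes = sorted({t.gene for t in tests})
    missing = [g for g in genes if g not in annotation]
    if missing:
        raise MapError(f"tested gene(s) missing from annotation: {missing}")
    verdicts: dict[str, dict] = {}
    for gene in genes:
        gene_tests = [t for t in tests if t.gene == gene]
        n_fail = sum(t.outcome == "fails" for t in gene_tests)
        dist = _division_distance(annotation[gene], region.interval)
        verdicts[gene] = {
            "allelic": n_fail >= 1 and dist <= radius_divisions,
            "failing_alleles": n_fail,
            "n_alleles": len(gene_tests),
            "division_distance": dist,
            "band": str(annotation[gene]),
        }
    return verdicts
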