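"""Fine-mapping arithmetic: tiling-PCR lesion localization and densitometry.

A structural lesion inside a tiled region reveals itself as amplicons that
fail to amplify or amplify at a size shifted from the wild-type expectation.
The candidate lesion interval is the union of anomalous amplicon intervals
minus every base covered by an amplicon that amplified at wild-type size
(those bases are demonstrably intact), reported as the minimal interval
containing the remaining bases.  Insertion sizing is the plain difference of
mutant and wild-type product sizes.  Semi-quantitative gel densitometry is
summarised as target/internal-control intensity ratios per genotype with
fold-changes against a reference genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, MapError

__all__ = [
    "Amplicon",
    "DensitometryMeasure",
    "LesionResult",
    "find_lesion_interval",
    "insertion_size",
    "relative_abundance",
]


@dataclass(frozen=True)
class Amplicon:
    """One primer pair: its wild-type interval and the observed PCR outcome."""

    id: str
    interval: GenomicInterval
    outcome: str  # "amplified" | "failed"
    observed_size: int | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("amplified", "failed"):
            raise ValueError(f"outcome must be amplified/failed, got {self.outcome!r}")
        if self.outcome == "amplified":
            if self.observed_size is None or self.observed_size <= 0:
                raise ValueError(f"amplicon {self.id}: amplified but no positive size")


@dataclass(frozen=True)
class DensitometryMeasure:
    """One lane intensity: target or internal-control band for a genotype."""

    genotype: str
    role: str  # "target" | "control"
    intensity: float

    def __post_init__(self) -> None:
        if self.role not in ("target", "control"):
            raise ValueError(f"role must be target/control, got {self.role!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class LesionResult:
    """Outcome of lesion localization over a tiling panel."""

    status: str  # "lesion" | "no_lesion" | "multi_lesion"
    interval: GenomicInterval | None
    clusters: tuple[GenomicInterval, ...] = ()
    anomalous: tuple[str, ...] = ()


def is_anomalous(a: Amplicon, size_tolerance: float = 0.10) -> bool:
    """Failed, or amplified at a size shifted beyond ``size_tolerance``."""
    if a.outcome == "failed":
        return True
    return abs(a.observed_size - a.interval.length) > size_tolerance * a.interval.length


def find_lesion_interval(
    panel: list[Amplicon], size_tolerance: float = 0.10
) -> LesionResult:
    """Locate the lesion from an overlapping-PCR panel (see module docstring).

    Returns a no-lesion result when every amplicon looks wild-type; when the
    anomalous amplicons fall in several disjoint clusters, all clusters are
    returned with a multi-lesion status (interval = widest cluster).
    """
    if not panel:
        raise MapError("empty amplicon panel")
    contigs = {a.interval.contig for a in panel}
    if len(contigs) > 1:
        raise MapError(f"panel spans multiple contigs: {sorted(contigs)}")
    contig = contigs.pop()

    bad = [a for a in panel if is_anomalous(a, size_tolerance)]
    if not bad:
        return LesionResult("no_lesion", None)
    good = [a for a in panel if not is_anomalous(a, size_tolerance)]

    lo = min(a.interval.start for a in panel)
    hi = max(a.interval.end for a in panel)
    mask = np.zeros(hi - lo + 1, dtype=bool)
    for a in bad:
        mask[a.interval.start - lo : a.interval.end - lo + 1] = True
    for a in good:
        mask[a.interval.start - lo : a.interval.end - lo + 1] = False

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        # every anomalous base is countermanded by a wild-type amplicon;
        # fall back to the anomalous union so the caller sees the conflict
        interval = GenomicInterval(
            contig, min(a.interval.start for a in bad), max(a.interval.end for a in bad)
        )
        return LesionResult("lesion", interval, anomalous=tuple(a.id for a in bad))

    # contiguous runs of candidate bases
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    clusters = tuple(
        GenomicInterval(contig, int(lo + idx[s]), int(lo + idx[e]))
        for s, e in zip(starts, ends)
    )
    anomalous = tuple(a.id for a in bad)
    if len(clusters) == 1:
        return LesionResult("lesion", clusters[0], clusters, anomalous)
    widest = max(clusters, key=lambda c: c.length)
    return LesionResult("multi_lesion", widest, clusters, anomalous)


def insertion_size(mutant_size: int, wildtype_size: int) -> int:
    """Size difference of the mutant product vs wild type (negative ⇒ deletion)."""
    if mutant_size <= 0 or wildtype_size <= 0:
        raise ValueError("product sizes must be positive")
    return mutant_size - wildtype_size


def relative_abundance(
    samples: list[DensitometryMeasure] | pd.DataFrame,
    reference: str | None = None,
) -> pd.DataFrame:
    """Target/control intensity ratios per genotype, with fold-change vs reference.

    Replicate lanes of the same genotype/role are averaged before the ratio.
    ``reference`` defaults to the first genotype in input order.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples[["genotype", "role", "intensity"]].copy()
    else:
        df = pd.DataFrame(
            [{"genotype": s.genotype, "role": s.role, "intensity": s.intensity} for s in samples]
        )
    if df.empty:
        raise MapError("no densitometry measures")
    wide = df.groupby(["genotype", "role"], sort=False)["intensity"].mean().unstack("role")
    for col in ("target", "control"):
        if col not in wide.columns or wide[col].isna().any():
            missing = (
                list(wide.index[wide[col].isna()]) if col in wide.columns else list(wide.index)
            )
            raise MapError(f"genotype(s) missing a {col} measure: {missing}")
    if (wide["control"] <= 0).any():
        bad = list(wide.index[wide["control"] <= 0])
        raise MapError(f"zero control intensity for genotype(s): {bad}")
    out = pd.DataFrame({"ratio": wide["target"] / wide["control"]})
    if reference is None:
        reference = df["genotype"].iloc[0]
    if reference not in out.index:
        raise MapError(f"reference genotype {reference!r} not among samples")
    out["fold_change"] = out["ratio"] / out.loc[reference, "ratio"]
    out.index.name = "genotype"
    return out
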