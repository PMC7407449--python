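"""TSV/JSON readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .complementation import AlleleTest, Deficiency
from .core import CytoBand, MapError, parse_cytoband, parse_cytointerval
from .linkage import PairCounts
from .molecular import Amplicon, DensitometryMeasure
from .core import GenomicInterval

__all__ = [
    "read_scored_males",
    "write_scored_males",
    "read_pair_counts",
    "write_pair_counts",
    "read_deficiency_panel",
    "write_deficiency_panel",
    "read_allele_tests",
    "read_gene_annotation",
    "read_amplicons",
    "write_amplicons",
    "read_densitometry",
    "read_stage_counts",
    "write_json",
]


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise MapError(f"{what}: missing column(s) {sorted(missing)}")


def read_scored_males(path) -> pd.DataFrame:
    """Scored-male TSV: marker columns (mut/wt) + locus_state (l/l+/unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, {"locus_state"}, "scored males")
    markers = [c for c in df.columns if c not in ("locus_state", "locus_true")]
    bad = set(df[markers].values.ravel()) - {"mut", "wt"}
    if bad:
        raise MapError(f"scored males: invalid allele values {sorted(bad)}")
    bad = set(df["locus_state"]) - {"l", "l+", "unknown"}
    if bad:
        raise MapError(f"scored males: invalid locus states {sorted(bad)}")
    return df


def write_scored_males(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pair_counts(path) -> list[PairCounts]:
    """Pair-count TSV: marker, parental, recombinant[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"marker", "parental", "recombinant"}, "pair counts")
    return [
        PairCounts(str(r["marker"]), int(r["parental"]), int(r["recombinant"]))
        for _, r in df.iterrows()
    ]


def write_pair_counts(counts: list[PairCounts], path) -> None:
    pd.DataFrame(
        [
            {"marker": c.marker, "parental": c.parental, "recombinant": c.recombinant}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_deficiency_panel(path) -> list[Deficiency]:
    """Panel TSV: id, arm, del_start, del_end, outcome."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, {"id", "arm", "del_start", "del_end", "outcome"}, "deficiency panel")
    return [
        Deficiency(
            r["id"],
            parse_cytointerval(f"{r['del_start']}-{r['del_end']}", arm=r["arm"]),
            r["outcome"],
        )
        for _, r in df.iterrows()
    ]


def write_deficiency_panel(panel: list[Deficiency], path) -> None:
    pd.DataFrame(
        [
            {
                "id": d.id,
                "arm": d.deleted.arm,
                "del_start": str(d.deleted.start),
                "del_end": str(d.deleted.end),
                "outcome": d.outcome,
            }
            for d in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def read_allele_tests(path) -> list[AlleleTest]:
    """Allele TSV: gene, allele, outcome."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, {"gene", "allele", "outcome"}, "allele tests")
    return [AlleleTest(r["gene"], r["allele"], r["outcome"]) for _, r in df.iterrows()]


def read_gene_annotation(path) -> dict[str, CytoBand]:
    """Annotation TSV: gene, arm, band."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, {"gene", "arm", "band"}, "gene annotation")
    return {r["gene"]: parse_cytoband(r["band"], arm=r["arm"]) for _, r in df.iterrows()}


def read_amplicons(path) -> list[Amplicon]:
    """Amplicon TSV: id, contig, start, end, outcome, observed_size."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"id", "contig", "start", "end", "outcome"}, "amplicons")
    out = []
    for _, r in df.iterrows():
        size = r.get("observed_size")
        size = None if pd.isna(size) else int(size)
        out.append(
            Amplicon(
                str(r["id"]),
                GenomicInterval(str(r["contig"]), int(r["start"]), int(r["end"])),
                str(r["outcome"]),
                size,
            )
        )
    return out


def write_amplicons(panel: list[Amplicon], path) -> None:
    pd.DataFrame(
        [
            {
                "id": a.id,
                "contig": a.interval.contig,
                "start": a.interval.start,
                "end": a.interval.end,
                "outcome": a.outcome,
                "observed_size": a.observed_size if a.observed_size is not None else "",
            }
            for a in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def read_densitometry(path) -> list[DensitometryMeasure]:
    """Densitometry TSV: genotype, role (target|control), intensity."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"genotype", "role", "intensity"}, "densitometry")
    return [
        DensitometryMeasure(str(r["genotype"]), str(r["role"]), float(r["intensity"]))
        for _, r in df.iterrows()
    ]


def read_stage_counts(path) -> pd.DataFrame:
    """Stage-count TSV: class, stage, count (long form) -> class × stage table."""
    df = pd.read_csv(path, sep="\t")
    _require(df, {"class", "stage", "count"}, "stage counts")
    stage_order = list(dict.fromkeys(df["stage"]))
    wide = df.pivot(index="class", columns="stage", values="count")[stage_order]
    return wide


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
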