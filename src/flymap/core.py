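"""Core domain types for classical Drosophila gene mapping.

Markers and genetic maps (centiMorgan scale), polytene cytogenetic bands
(arm / numbered division / letter / sub-band, e.g. ``3L:71F4``), cytogenetic
and genomic intervals, and marker haplotypes.  These are the shared currency
of the recombination-mapping, complementation and fine-mapping stages.

Conventions
-----------
* Genomic coordinates are 1-based and fully inclusive (``start..end``), so a
  single base has length 1.
* Cytogenetic bands order within an arm by (division, letter, sub-band); a
  band with no sub-band sorts before sub-band 1.
* An interval endpoint written without a sub-band (``72A``) denotes the full
  lettered band and is expanded to ``72A1``–``72A<max>`` when used as an
  interval bound (``MAX_SUBBAND`` sub-bands per letter by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ARMS",
    "MAX_SUBBAND",
    "CytoBand",
    "CytoInterval",
    "GenomicInterval",
    "Haplotype",
    "Marker",
    "MarkerMap",
    "MapError",
    "BandParseError",
    "band_lattice",
    "compare_cytoband",
    "format_cytoband",
    "interval_length",
    "load_marker_map",
    "parse_cytoband",
    "parse_cytointerval",
    "rucuca_map",
]

ARMS = ("X", "2L", "2R", "3L", "3R", "4")

#: polytene division ranges per chromosome arm (standard Bridges numbering)
_ARM_DIVISIONS = {
    "X": (1, 20),
    "2L": (21, 40),
    "2R": (41, 60),
    "3L": (61, 80),
    "3R": (81, 100),
    "4": (101, 102),
}

#: sub-bands assumed per lettered band when an endpoint omits the sub-band.
MAX_SUBBAND = 20

_LETTERS = "ABCDEF"


class BandParseError(ValueError):
    """Raised when a cytogenetic band string cannot be parsed."""


class MapError(ValueError):
    """Raised for invalid maps, markers or incomparable bands."""


def _infer_arm(division: int) -> str:
    for arm, (lo, hi) in _ARM_DIVISIONS.items():
        if lo <= division <= hi:
            return arm
    raise BandParseError(f"division {division} is outside every known arm")


@total_ordering
@dataclass(frozen=True)
class CytoBand:
    """One polytene band, e.g. 3L division 71, letter F, sub-band 4 (``71F4``)."""

    arm: str
    division: int
    letter: str
    subband: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise BandParseError(f"unknown chromosome arm {self.arm!r}")
        if self.letter not in _LETTERS:
            raise BandParseError(f"band letter must be one of {_LETTERS}, got {self.letter!r}")
        lo, hi = _ARM_DIVISIONS[self.arm]
        if not lo <= self.division <= hi:
            raise BandParseError(
                f"division {self.division} is not on arm {self.arm} ({lo}-{hi})"
            )
        if self.subband is not None and self.subband < 1:
            raise BandParseError(f"sub-band must be positive, got {self.subband}")

    def _key(self) -> tuple[int, int, int]:
        # missing sub-band sorts before sub-band 1
        return (self.division, _LETTERS.index(self.letter), self.subband or 0)

    def __lt__(self, other: "CytoBand") -> bool:
        if not isinstance(other, CytoBand):
            return NotImplemented
        if self.arm != other.arm:
            raise MapError(f"bands on different arms are incomparable: {self} vs {other}")
        return self._key() < other._key()

    def __str__(self) -> str:
        sub = "" if self.subband is None else str(self.subband)
        return f"{self.division}{self.letter}{sub}"


_BAND_RE = re.compile(
    r"^(?:(?P<arm>X|2L|2R|3L|3R|4)\s*:\s*)?"
    r"(?P<division>\d{1,3})(?P<letter>[A-F])(?P<subband>\d+)?$"
)


def parse_cytoband(text: str, arm: str | None = None) -> CytoBand:
    """Parse a band string like ``"72A1"``, ``"71F"`` or ``"3L:71F4"``.

    The arm may be given explicitly in the string, supplied via ``arm``
    (context), or inferred from the division number using the standard
    division→arm ranges.
    """
    m = _BAND_RE.match(text.strip())
    if m is None:
        raise BandParseError(f"malformed band string: {text!r}")
    division = int(m.group("division"))
    band_arm = m.group("arm") or arm or _infer_arm(division)
    sub = m.group("subband")
    return CytoBand(band_arm, division, m.group("letter"), int(sub) if sub else None)


def format_cytoband(band: CytoBand, with_arm: bool = False) -> str:
    return f"{band.arm}:{band}" if with_arm else str(band)


def compare_cytoband(a: CytoBand, b: CytoBand) -> int:
    """Total order within an arm: -1, 0 or +1 by (division, letter, sub-band)."""
    if a.arm != b.arm:
        raise MapError(f"bands on different arms are incomparable: {a} vs {b}")
    return (a._key() > b._key()) - (a._key() < b._key())


@dataclass(frozen=True)
class CytoInterval:
    """A closed cytogenetic interval (both endpoints included), one arm.

    Endpoints lacking a sub-band are expanded: the start to sub-band 1 and the
    end to sub-band ``max_subband``, so ``71F–72A`` means ``71F1``–``72A20``.
    """

    start: CytoBand
    end: CytoBand
    max_subband: int = MAX_SUBBAND

    def __post_init__(self) -> None:
        if self.start.arm != self.end.arm:
            raise MapError(f"interval endpoints on different arms: {self.start} / {self.end}")
        start, end = self.start, self.end
        if start.subband is None:
            start = CytoBand(start.arm, start.division, start.letter, 1)
        if end.subband is None:
            end = CytoBand(end.arm, end.division, end.letter, self.max_subband)
        if compare_cytoband(start, end) > 0:
            raise MapError(f"interval start {self.start} after end {self.end}")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def arm(self) -> str:
        return self.start.arm

    def contains(self, band: CytoBand) -> bool:
        if band.arm != self.arm:
            return False
        b = band if band.subband is not None else CytoBand(band.arm, band.division, band.letter, 1)
        return compare_cytoband(self.start, b) <= 0 and compare_cytoband(b, self.end) <= 0

    def overlaps(self, other: "CytoInterval") -> bool:
        if other.arm != self.arm:
            return False
        return (
            compare_cytoband(self.start, other.end) <= 0
            and compare_cytoband(other.start, self.end) <= 0
        )

    def intersect(self, other: "CytoInterval") -> "CytoInterval | None":
        if not self.overlaps(other):
            return None
        start = max(self.start, other.start)
        end = min(self.end, other.end)
        return CytoInterval(start, end, self.max_subband)

    def __str__(self) -> str:
        return f"{self.arm}:{self.start}-{self.end}"


_INTERVAL_SPLIT_RE = re.compile(r"\s*[-–—]\s*")


def parse_cytointerval(text: str, arm: str | None = None, max_subband: int = MAX_SUBBAND) -> CytoInterval:
    """Parse interval strings like ``"71F4-F5"``, ``"71F1-72A1"`` or ``"72A1"``.

    The right endpoint may omit the division (``71F4-F5``) or the division and
    letter (``71F4-5``), inheriting them from the left endpoint.
    """
    parts = _INTERVAL_SPLIT_RE.split(text.strip())
    if len(parts) == 1:
        b = parse_cytoband(parts[0], arm)
        return CytoInterval(b, b, max_subband)
    if len(parts) != 2:
        raise BandParseError(f"malformed interval string: {text!r}")
    start = parse_cytoband(parts[0], arm)
    right = parts[1].strip()
    if re.fullmatch(r"\d+", right):  # bare sub-band: "71F4-5"
        end = CytoBand(start.arm, start.division, start.letter, int(right))
    elif re.fullmatch(r"[A-F]\d*", right):  # letter(+subband): "71F4-F5"
        sub = right[1:]
        end = CytoBand(start.arm, start.division, right[0], int(sub) if sub else None)
    else:
        end = parse_cytoband(right, start.arm)
    return CytoInterval(start, end, max_subband)


def band_lattice(
    arm: str,
    div_lo: int,
    div_hi: int,
    max_subband: int = MAX_SUBBAND,
) -> list[CytoBand]:
    """All bands on ``arm`` between divisions ``div_lo``..``div_hi``, in order."""
    if div_lo > div_hi:
        raise MapError("div_lo must not exceed div_hi")
    return [
        CytoBand(arm, d, letter, s)
        for d in range(div_lo, div_hi + 1)
        for letter in _LETTERS
        for s in range(1, max_subband + 1)
    ]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, fully inclusive genomic interval, e.g. ``3L:15826279..15827223``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise MapError(f"invalid interval {self.contig}:{self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}..{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        m = re.match(r"^\s*([\w]+)\s*:\s*(\d+)\s*\.\.\s*(\d+)\s*$", text)
        if m is None:
            raise MapError(f"malformed genomic interval: {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


def interval_length(g: GenomicInterval) -> int:
    """Length in base pairs of a 1-based inclusive interval (end − start + 1)."""
    return g.length


@dataclass(frozen=True)
class Marker:
    """A visible recessive marker with a genetic-map position and a band."""

    name: str
    cm: float
    band: CytoBand
    recessive: bool = True

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise MapError(f"marker {self.name}: cM position must be non-negative")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers on one chromosome, strictly increasing in cM."""

    chromosome: str
    markers: tuple[Marker, ...]

    def __init__(self, chromosome: str, markers: Sequence[Marker]):
        markers = tuple(markers)
        if len(markers) < 2:
            raise MapError("a marker map needs at least 2 markers")
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise MapError("marker names must be unique")
        cms = [m.cm for m in markers]
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise MapError("markers must be sorted by strictly increasing cM")
        object.__setattr__(self, "chromosome", chromosome)
        object.__setattr__(self, "markers", markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def positions(self) -> list[float]:
        return [m.cm for m in self.markers]

    @property
    def span(self) -> float:
        return self.markers[-1].cm - self.markers[0].cm

    def __getitem__(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise MapError(f"marker {name!r} not in map")

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)


@dataclass(frozen=True)
class Haplotype:
    """Per-marker allele states plus the lethal-locus state of one chromosome.

    ``alleles`` holds one state per map marker, ``"mut"`` or ``"wt"``;
    ``locus_state`` is ``"l"`` (carries the lethal), ``"l+"`` or ``"unknown"``.
    """

    alleles: tuple[str, ...]
    locus_state: str = "unknown"

    def __post_init__(self) -> None:
        bad = set(self.alleles) - {"mut", "wt"}
        if bad:
            raise MapError(f"invalid allele states: {sorted(bad)}")
        if self.locus_state not in ("l", "l+", "unknown"):
            raise MapError(f"invalid locus state: {self.locus_state!r}")


# ---------------------------------------------------------------------------
# packaged marker map
# ---------------------------------------------------------------------------

#: Standard chromosome-3 "rucuca" multiple-marker map.  Only thread's position
#: (43.2 cM, 72D1) is fixed by the mapping narrative; the remaining positions
#: are the standard D. melanogaster chromosome-3 values and can be overridden
#: by loading a user map (see :func:`load_marker_map`).
_RUCUCA_ROWS = [
    ("ru", 0.0, "61F3"),
    ("h", 26.5, "66D10"),
    ("th", 43.2, "72D1"),
    ("st", 44.0, "73A3"),
    ("cu", 50.0, "86D1"),
    ("sr", 62.0, "90E1"),
    ("e", 70.7, "93C7"),
    ("ca", 100.7, "99C1"),
]


def rucuca_map() -> MarkerMap:
    """The packaged chromosome-3 ru–h–th–st–cu–sr–e–ca marker map."""
    return MarkerMap(
        "3", [Marker(n, cm, parse_cytoband(b)) for n, cm, b in _RUCUCA_ROWS]
    )


def load_marker_map(path) -> MarkerMap:
    """Load a marker map from a TSV with columns ``name chrom cm band``."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str, "band": str})
    required = {"name", "chrom", "cm", "band"}
    if not required.issubset(df.columns):
        raise MapError(f"marker map TSV must have columns {sorted(required)}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise MapError("marker map must cover exactly one chromosome")
    markers = [
        Marker(r["name"], float(r["cm"]), parse_cytoband(r["band"]))
        for _, r in df.iterrows()
    ]
    return MarkerMap(str(chroms[0]), markers)


def write_marker_map(mmap: MarkerMap, path) -> None:
    df = pd.DataFrame(
        {
            "name": mmap.names,
            "chrom": mmap.chromosome,
            "cm": mmap.positions,
            "band": [format_cytoband(m.band, with_arm=True) for m in mmap],
        }
    )
    df.to_csv(path, sep="\t", index=False)
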