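"""Two-point recombination-frequency mapping of a lethal locus.

The mapping cross keeps the lethal mutation and a multiply-marked chromosome
in repulsion phase in F2 females.  Each scored F3 male carries one maternal
(possibly recombinant) chromosome; his lethal-locus state is read out by a
testcross against mutation/balancer females (absence of the non-balancer
class ⇒ the chromosome carries the lethal).  For each visible marker the
males partition into parental (marker-wild ∧ l, or marker-mutant ∧ l+) and
recombinant chromosomes, and the recombination fraction is

    RF = 100 · R / (P + R)   [percent],

with an exact (Clopper–Pearson) binomial confidence interval.  RF percent is
read directly as centiMorgans (identity map function) by default, matching
the published arithmetic; Haldane and Kosambi corrections are available.

Locus placement (``flank_subtraction``) anchors on the minimum-RF marker,
chooses the side (left/right) on which the marker-implied positions
pos(m) ∓ rf(m) cluster most tightly, and reports the [min, max] of the
implied positions over an informative marker set — by default the two
smallest-RF markers.  Alongside this point interval an uncertainty interval
(``ci_bounds``) is reported, expanded by each informative marker's exact CI;
see docs/methods.md for why the point interval is a display convention while
coverage statements belong to the CI interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MapError, MarkerMap

__all__ = [
    "PairCounts",
    "RFEstimate",
    "PlacementResult",
    "classify_pair",
    "estimate_rf",
    "format_rf",
    "infer_l_status",
    "place_locus",
    "pool_counts",
    "rf_to_cm",
]


@dataclass(frozen=True)
class PairCounts:
    """Parental/recombinant tallies for one marker–locus pair."""

    marker: str
    parental: int
    recombinant: int
    excluded: int = 0  # males with unknown locus state, dropped from P+R

    def __post_init__(self) -> None:
        if self.parental < 0 or self.recombinant < 0 or self.excluded < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.parental + self.recombinant


@dataclass(frozen=True)
class RFEstimate:
    """Recombination fraction in percent with an exact binomial CI."""

    marker: str
    rf: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf <= 100.0):
            raise ValueError("rf must be in [0, 100]")
        if not (self.ci_low <= self.rf <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


@dataclass(frozen=True)
class PlacementResult:
    """Locus placement relative to the anchor marker.

    ``bounds`` is the point flank-subtraction interval; ``ci_bounds`` the
    CI-expanded interval used for coverage statements.  For the
    ``least_squares`` method ``point`` is the grid minimiser and ``ci_bounds``
    a parametric-bootstrap interval.
    """

    side: str
    anchor: str
    bounds: tuple[float, float]
    ci_bounds: tuple[float, float]
    method: str
    markers: tuple[str, ...]
    point: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.bounds[0] > self.bounds[1]:
            raise ValueError("bounds must be ordered")


def infer_l_status(
    non_balancer_adults: int, total_scored: int, min_total: int = 20
) -> str:
    """Call the lethal-locus state of a tested chromosome from testcross adults.

    ``l`` when no non-balancer adults emerge from an adequately sized cross,
    ``l+`` when any non-balancer adult emerges, ``unknown`` when the cross is
    too small to call absence.
    """
    if non_balancer_adults < 0 or total_scored < 0:
        raise ValueError("counts must be non-negative")
    if non_balancer_adults > total_scored:
        raise ValueError("non-balancer adults cannot exceed total scored")
    if non_balancer_adults > 0:
        return "l+"
    return "l" if total_scored >= min_total else "unknown"


def classify_pair(males: pd.DataFrame, marker: str) -> PairCounts:
    """Tally parental vs recombinant chromosomes for one marker.

    In repulsion phase the parental classes are (marker wild ∧ l) and
    (marker mutant ∧ l+); everything else with a known locus state is
    recombinant.  Males with unknown state are excluded and counted in
    ``excluded``.
    """
    if marker not in males.columns:
        raise MapError(f"marker {marker!r} not in scored-male table")
    state = males["locus_state"]
    known = males[state.isin(["l", "l+"])]
    excluded = len(males) - len(known)
    alleles = known[marker]
    parental = int(
        ((alleles == "wt") & (known["locus_state"] == "l")).sum()
        + ((alleles == "mut") & (known["locus_state"] == "l+")).sum()
    )
    recombinant = len(known) - parental
    return PairCounts(marker, parental, recombinant, excluded)


def estimate_rf(counts: PairCounts, ci_level: float = 0.95) -> RFEstimate:
    """RF = 100·R/(P+R) with a Clopper–Pearson CI on R successes in P+R trials."""
    n = counts.n
    if n == 0:
        raise ValueError(f"{counts.marker}: P + R = 0, RF undefined")
    r = counts.recombinant
    rf = 100.0 * r / n
    alpha = 1.0 - ci_level
    lo = 0.0 if r == 0 else float(stats.beta.ppf(alpha / 2, r, n - r + 1))
    hi = 1.0 if r == n else float(stats.beta.ppf(1 - alpha / 2, r + 1, n - r))
    return RFEstimate(counts.marker, rf, 100.0 * lo, 100.0 * hi, n)


def pool_counts(replicates: list[PairCounts]) -> PairCounts:
    """Component-wise sum of replicate tallies for one marker."""
    if not replicates:
        raise ValueError("no replicates to pool")
    markers = {c.marker for c in replicates}
    if len(markers) > 1:
        raise MapError(f"cannot pool counts across markers: {sorted(markers)}")
    return PairCounts(
        replicates[0].marker,
        sum(c.parental for c in replicates),
        sum(c.recombinant for c in replicates),
        sum(c.excluded for c in replicates),
    )


def rf_to_cm(rf_percent: float, map_function: str = "identity") -> float:
    """Convert an RF percent to map distance in cM under a map function."""
    r = rf_percent / 100.0
    if map_function == "identity":
        return rf_percent
    if map_function == "haldane":
        if r >= 0.5:
            return math.inf
        return -50.0 * math.log(1.0 - 2.0 * r)
    if map_function == "kosambi":
        if r >= 0.5:
            return math.inf
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown map function {map_function!r}")


def format_rf(rf: float, decimals: int = 2) -> str:
    """Display an RF percent truncated (not rounded) to ``decimals`` places."""
    if not (0.0 <= rf <= 100.0):
        raise ValueError("rf must be in [0, 100]")
    scale = 10**decimals
    truncated = math.floor(rf * scale + 1e-9) / scale
    return f"{truncated:.{decimals}f}"


def _pick_anchor(estimates: dict[str, RFEstimate]) -> str:
    # minimal rf; ties broken toward larger n
    return min(estimates.values(), key=lambda e: (e.rf, -e.n)).marker


def _informative_set(
    estimates: dict[str, RFEstimate], anchor: str
) -> list[str]:
    """Default informative set: the two smallest-RF markers.

    The anchor is excluded only when its RF is degenerate at zero (no
    recombinant chromosome observed), in which case it cannot resolve a side.
    """
    ranked = sorted(estimates.values(), key=lambda e: (e.rf, -e.n))
    pool = [e for e in ranked if not (e.marker == anchor and e.rf == 0.0)]
    return [e.marker for e in pool[:2]]


def place_locus(
    estimates: dict[str, RFEstimate] | list[RFEstimate],
    marker_map: MarkerMap,
    method: str = "flank_subtraction",
    informative: list[str] | None = None,
    map_function: str = "identity",
    grid_step: float = 0.01,
    n_bootstrap: int = 200,
    ci_level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> PlacementResult:
    """Place the lethal locus on the cM map from per-marker RF estimates."""
    if isinstance(estimates, list):
        estimates = {e.marker: e for e in estimates}
    if len(estimates) < 2:
        raise MapError("placement needs at least 2 marker estimates")
    for name in estimates:
        if name not in marker_map:
            raise MapError(f"estimate for unknown marker {name!r}")
    if method == "flank_subtraction":
        return _place_flank_subtraction(estimates, marker_map, informative, map_function)
    if method == "least_squares":
        return _place_least_squares(
            estimates, marker_map, map_function, grid_step, n_bootstrap, ci_level, rng
        )
    raise ValueError(f"unknown placement method {method!r}")


def _implied(pos: float, d: float, side: str) -> float:
    return pos - d if side == "left" else pos + d


def _place_flank_subtraction(
    estimates: dict[str, RFEstimate],
    marker_map: MarkerMap,
    informative: list[str] | None,
    map_function: str,
) -> PlacementResult:
    anchor = _pick_anchor(estimates)
    anchor_est = estimates[anchor]
    note = ""
    ties = [e.marker for e in estimates.values() if e.rf == anchor_est.rf]
    if len(ties) > 1:
        note = f"anchor tie among {sorted(ties)} broken toward larger n"

    # degenerate: anchor shows zero recombination -> locus at the anchor
    if anchor_est.rf == 0.0:
        pos = marker_map[anchor].cm
        lo_ci = pos - rf_to_cm(anchor_est.ci_high, map_function)
        hi_ci = pos + rf_to_cm(anchor_est.ci_high, map_function)
        return PlacementResult(
            side="at",
            anchor=anchor,
            bounds=(pos, pos),
            ci_bounds=(lo_ci, hi_ci),
            method="flank_subtraction",
            markers=(anchor,),
            note=(note + " zero RF at anchor: degenerate placement").strip(),
        )

    if informative is None:
        informative = _informative_set(estimates, anchor)
    if len(informative) < 2:
        raise MapError("fewer than 2 informative markers")

    dists = {m: rf_to_cm(estimates[m].rf, map_function) for m in informative}
    positions = {m: marker_map[m].cm for m in informative}

    # side on which the implied positions cluster most tightly
    rss = {}
    for side in ("left", "right"):
        implied = [_implied(positions[m], dists[m], side) for m in informative]
        mean = sum(implied) / len(implied)
        rss[side] = sum((x - mean) ** 2 for x in implied)
    side = "left" if rss["left"] <= rss["right"] else "right"

    implied = [_implied(positions[m], dists[m], side) for m in informative]
    bounds = (min(implied), max(implied))

    # CI-expanded interval: widest extent implied by each marker's exact CI
    ci_implied = []
    for m in informative:
        lo_d = rf_to_cm(estimates[m].ci_low, map_function)
        hi_d = rf_to_cm(estimates[m].ci_high, map_function)
        ci_implied.append(_implied(positions[m], hi_d, side))
        ci_implied.append(_implied(positions[m], lo_d, side))
    ci_bounds = (min(ci_implied), max(ci_implied))

    return PlacementResult(
        side=side,
        anchor=anchor,
        bounds=bounds,
        ci_bounds=ci_bounds,
        method="flank_subtraction",
        markers=tuple(informative),
        note=note,
    )


def _place_least_squares(
    estimates: dict[str, RFEstimate],
    marker_map: MarkerMap,
    map_function: str,
    grid_step: float,
    n_bootstrap: int,
    ci_level: float,
    rng: np.random.Generator | None,
) -> PlacementResult:
    names = list(estimates)
    pos = np.array([marker_map[m].cm for m in names])
    dist = np.array([rf_to_cm(estimates[m].rf, map_function) for m in names])
    finite = np.isfinite(dist)
    if finite.sum() < 2:
        raise MapError("fewer than 2 informative markers")
    pos, dist = pos[finite], dist[finite]
    names = [n for n, f in zip(names, finite) if f]
    n = np.array([estimates[m].n for m in names])

    lo = max(0.0, marker_map.markers[0].cm - 10.0)
    hi = marker_map.markers[-1].cm + 10.0
    grid = np.arange(lo, hi + grid_step, grid_step)

    def argmin_x(d: np.ndarray) -> float:
        resid = d[None, :] - np.abs(pos[None, :] - grid[:, None])
        return float(grid[np.argmin((resid**2).sum(axis=1))])

    point = argmin_x(dist)

    rng = rng if rng is not None else np.random.default_rng(0)
    p = np.clip(dist / 100.0, 0.0, 0.5)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        r_b = rng.binomial(n, p)
        d_b = 100.0 * r_b / n
        boots[b] = argmin_x(d_b)
    alpha = 1.0 - ci_level
    ci = (float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2)))

    anchor = _pick_anchor(estimates)
    side = "left" if point <= marker_map[anchor].cm else "right"
    return PlacementResult(
        side=side,
        anchor=anchor,
        bounds=(point, point),
        ci_bounds=ci,
        method="least_squares",
        markers=tuple(names),
        point=point,
    )
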