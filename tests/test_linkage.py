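"""Recombination-fraction estimation, pooling, and locus placement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flymap.core import MapError
from flymap.linkage import (
    PairCounts,
    RFEstimate,
    classify_pair,
    estimate_rf,
    format_rf,
    infer_l_status,
    place_locus,
    pool_counts,
    rf_to_cm,
)

MARKERS = ["ru", "h", "th", "st", "cu", "sr", "e", "ca"]


class TestInferLStatus:
    @pytest.mark.parametrize(
        "non_bal, total, expected",
        [(0, 40, "l"), (12, 40, "l+"), (0, 5, "unknown"), (1, 5, "l+"), (0, 20, "l")],
    )
    def test_rule(self, non_bal, total, expected):
        assert infer_l_status(non_bal, total, min_total=20) == expected

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            infer_l_status(-1, 10)
        with pytest.raises(ValueError):
            infer_l_status(11, 10)


def _hand_table():
    """20 males with a known manual tally for marker 'm'."""
    rows = (
        [{"m": "wt", "locus_state": "l"}] * 7      # parental
        + [{"m": "mut", "locus_state": "l+"}] * 5  # parental
        + [{"m": "wt", "locus_state": "l+"}] * 3   # recombinant
        + [{"m": "mut", "locus_state": "l"}] * 2   # recombinant
        + [{"m": "wt", "locus_state": "unknown"}] * 3
    )
    return pd.DataFrame(rows)


class TestClassifyPair:
    def test_counts_match_manual_tally(self):
        pc = classify_pair(_hand_table(), "m")
        # brute-force oracle: explicit enumeration over the four known classes
        assert (pc.parental, pc.recombinant, pc.excluded) == (12, 5, 3)
        assert pc.n == 17

    def test_row_order_invariance(self):
        df = _hand_table()
        shuffled = df.sample(frac=1.0, random_state=3)
        a, b = classify_pair(df, "m"), classify_pair(shuffled, "m")
        assert (a.parental, a.recombinant) == (b.parental, b.recombinant)

    def test_intact_mutant_chromosomes_give_zero_recombinants(self):
        df = pd.DataFrame([{"m": "wt", "locus_state": "l"}] * 9)
        pc = classify_pair(df, "m")
        assert pc.recombinant == 0 and pc.parental == 9

    def test_phase_symmetry(self):
        """Swapping mut<->wt together with l<->l+ leaves RF unchanged."""
        df = _hand_table()
        swapped = df.replace({"m": {"wt": "mut", "mut": "wt"},
                              "locus_state": {"l": "l+", "l+": "l"}})
        a = estimate_rf(classify_pair(df, "m"))
        b = estimate_rf(classify_pair(swapped, "m"))
        assert a.rf == pytest.approx(b.rf)

    def test_missing_marker_raises(self):
        with pytest.raises(MapError):
            classify_pair(_hand_table(), "absent")


class TestEstimateRF:
    @pytest.mark.parametrize(
        "p, r, printed",
        [(62, 51, "45.13"), (110, 3, "2.65"), (86, 27, "23.89"), (79, 34, "30.08")],
    )
    def test_published_tallies(self, p, r, printed):
        est = estimate_rf(PairCounts("m", p, r))
        assert format_rf(est.rf) == printed
        assert est.n == 113

    def test_zero_recombinants(self):
        est = estimate_rf(PairCounts("m", 50, 0))
        assert est.rf == 0.0 and est.ci_low == 0.0 and est.ci_high > 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            estimate_rf(PairCounts("m", 0, 0))

    @pytest.mark.parametrize("r, n", [(3, 113), (0, 50), (51, 113), (12, 982)])
    def test_ci_matches_binomial_cdf_bisection(self, r, n):
        """Clopper–Pearson endpoints from a from-scratch bisection on the
        binomial CDF."""
        est = estimate_rf(PairCounts("m", n - r, r), ci_level=0.95)

        def cdf(k, n, p):
            return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))

        def bisect(f, lo, hi, tol=1e-10):
            while hi - lo > tol:
                mid = (lo + hi) / 2
                if f(mid):
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        if r > 0:
            lo = bisect(lambda p: 1 - cdf(r - 1, n, p) < 0.025, 0.0, 1.0)
            assert est.ci_low == pytest.approx(100 * lo, abs=1e-4)
        else:
            assert est.ci_low == 0.0
        if r < n:
            hi = bisect(lambda p: cdf(r, n, p) > 0.025, 0.0, 1.0)
            assert est.ci_high == pytest.approx(100 * hi, abs=1e-4)


class TestPoolCounts:
    def test_replicate_pooling(self):
        reps = [PairCounts("h", 89, 18), PairCounts("h", 185, 40), PairCounts("h", 96, 22)]
        pooled = pool_counts(reps)
        assert (pooled.parental, pooled.recombinant) == (370, 80)
        assert estimate_rf(pooled).rf == pytest.approx(17.78, abs=0.005)

    def test_single_replicate_identity(self):
        c = PairCounts("h", 10, 2)
        assert pool_counts([c]) == c

    def test_mixed_markers_raise(self):
        with pytest.raises(MapError):
            pool_counts([PairCounts("h", 1, 1), PairCounts("st", 1, 1)])

    def test_pooling_equals_concatenated_table(self):
        """Pooling replicate tallies = tallying the concatenated male table."""
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(3):
            n = 40
            alleles = rng.choice(["mut", "wt"], size=n)
            states = rng.choice(["l", "l+"], size=n)
            frames.append(pd.DataFrame({"m": alleles, "locus_state": states}))
        pooled = pool_counts([classify_pair(f, "m") for f in frames])
        whole = classify_pair(pd.concat(frames, ignore_index=True), "m")
        assert (pooled.parental, pooled.recombinant) == (whole.parental, whole.recombinant)


class TestPlacement:
    def _est(self, marker, rf, n=1000):
        return RFEstimate(marker, rf, max(rf - 1, 0.0), rf + 1, n)

    def test_refined_rf_bounds(self, rucuca):
        res = place_locus({"st": self._est("st", 1.23), "cu": self._est("cu", 8.29)}, rucuca)
        assert res.side == "left"
        assert res.bounds == (pytest.approx(41.71), pytest.approx(42.77))
        assert set(res.markers) == {"st", "cu"}

    def test_informative_set_defaults_to_two_smallest(self, rucuca):
        ests = {m: self._est(m, rf) for m, rf in
                [("h", 17.78), ("st", 1.23), ("cu", 8.29)]}
        res = place_locus(ests, rucuca)
        assert set(res.markers) == {"st", "cu"}
        assert res.anchor == "st"

    def test_zero_rf_degenerate(self, rucuca):
        ests = {"th": RFEstimate("th", 0.0, 0.0, 3.2, 113), "st": self._est("st", 4.42)}
        res = place_locus(ests, rucuca)
        assert res.bounds == (43.2, 43.2)
        assert res.side == "at"
        assert res.ci_bounds[0] < 43.2 < res.ci_bounds[1]

    def test_single_estimate_raises(self, rucuca):
        with pytest.raises(MapError):
            place_locus({"st": self._est("st", 1.0)}, rucuca)

    def test_least_squares_matches_fine_grid_oracle(self, rucuca):
        ests = {m: RFEstimate(m, rf, rf, rf, 113) for m, rf in
                [("th", 2.65), ("st", 4.42), ("cu", 7.07), ("h", 30.08)]}
        res = place_locus(ests, rucuca, method="least_squares", n_bootstrap=50,
                          rng=np.random.default_rng(0))
        pos = np.array([rucuca[m].cm for m in ests])
        rf = np.array([e.rf for e in ests.values()])
        grid = np.arange(0.0, rucuca.markers[-1].cm + 10.0, 0.001)
        sse = ((rf[None, :] - np.abs(pos[None, :] - grid[:, None])) ** 2).sum(axis=1)
        oracle = grid[np.argmin(sse)]
        assert res.point == pytest.approx(oracle, abs=0.011)
        assert res.ci_bounds[0] <= res.point <= res.ci_bounds[1]

    def test_anchor_tie_broken_toward_larger_n(self, rucuca):
        ests = {"th": RFEstimate("th", 5.0, 4.0, 6.0, 50),
                "st": RFEstimate("st", 5.0, 4.0, 6.0, 500),
                "cu": self._est("cu", 9.0)}
        res = place_locus(ests, rucuca)
        assert res.anchor == "st"
        assert "tie" in res.note


class TestMapFunctions:
    def test_identity_is_passthrough(self):
        assert rf_to_cm(12.5, "identity") == 12.5

    def test_haldane_kosambi_inverse_of_map(self):
        # d -> rf -> d round trip through the closed forms
        for d in (1.0, 10.0, 30.0):
            rf_h = 100 * (1 - math.exp(-2 * d / 100)) / 2
            assert rf_to_cm(rf_h, "haldane") == pytest.approx(d)
            rf_k = 100 * math.tanh(2 * d / 100) / 2
            assert rf_to_cm(rf_k, "kosambi") == pytest.approx(d)

    def test_free_recombination_unmappable(self):
        assert rf_to_cm(50.0, "haldane") == math.inf


class TestFormatRF:
    @pytest.mark.parametrize(
        "rf, expected",
        [(7.0796, "7.07"), (45.1327, "45.13"), (30.0884, "30.08"), (0.0, "0.00")],
    )
    def test_truncation_convention(self, rf, expected):
        assert format_rf(rf) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            format_rf(101.0)
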