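"""Synthetic-experiment generators: crossover process, testcross scoring,
deficiency panels, tiling panels and stage survival."""

import numpy as np
import pandas as pd
import pytest

from flymap.complementation import solve_region
from flymap.core import GenomicInterval, band_lattice, parse_cytoband
from flymap.molecular import find_lesion_interval
from flymap.simulate import (
    CrossoverModel,
    DeficiencyPanelSpec,
    ExperimentSpec,
    TilingSpec,
    simulate_deficiency_panel,
    simulate_gametes,
    simulate_mapping_experiment,
    simulate_stage_survival,
    simulate_tiling_pcr,
)


def _recomb_fraction(gametes, i, j):
    a = np.array([[x == "mut" for x in g.alleles] for g in gametes])
    return float((a[:, i] != a[:, j]).mean())


class TestSimulateGametes:
    def test_zero_crossovers_all_parental(self, rucuca):
        g = simulate_gametes(rucuca, CrossoverModel(kind="fixed_count", count=0), 200, seed=0)
        for h in g:
            assert len(set(h.alleles)) == 1  # fully mutant or fully wild

    def test_haldane_matches_map_function(self, rucuca):
        """Adjacent-pair recombinant fractions within 3 binomial SE of the
        closed-form Haldane expectation at n = 10,000."""
        n = 10_000
        g = simulate_gametes(rucuca, CrossoverModel(), n, seed=1)
        pos = rucuca.positions
        for i in range(len(pos) - 1):
            d = pos[i + 1] - pos[i]
            expected = (1 - np.exp(-2 * d / 100)) / 2
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(_recomb_fraction(g, i, i + 1) - expected) < 3 * se

    def test_identity_map_far_markers_free_recombination(self):
        from flymap.core import Marker, MarkerMap, parse_cytoband

        two = MarkerMap(
            "3",
            [
                Marker("a", 0.0, parse_cytoband("61A1")),
                Marker("b", 60.0, parse_cytoband("80F1")),
            ],
        )
        n = 10_000
        g = simulate_gametes(
            two, CrossoverModel(kind="haldane", map_function="identity"), n, seed=2
        )
        rf = _recomb_fraction(g, 0, 1)
        assert abs(rf - 0.5) < 3 * np.sqrt(0.25 / n)

    @pytest.mark.parametrize(
        "model",
        [
            CrossoverModel(kind="fixed_count", count=2),
            CrossoverModel(kind="gamma_interference", shape=4.0),
        ],
    )
    def test_alternative_models_produce_valid_haplotypes(self, rucuca, model):
        g = simulate_gametes(rucuca, model, 50, seed=3)
        assert len(g) == 50
        assert all(len(h.alleles) == len(rucuca) for h in g)

    def test_reproducible_given_seed(self, rucuca):
        a = simulate_gametes(rucuca, CrossoverModel(), 100, seed=7, locus_cm=42.3)
        b = simulate_gametes(rucuca, CrossoverModel(), 100, seed=7, locus_cm=42.3)
        assert a == b

    def test_nonpositive_n_raises(self, rucuca):
        with pytest.raises(ValueError):
            simulate_gametes(rucuca, CrossoverModel(), 0, seed=0)


class TestMappingExperiment:
    def _spec(self, **kw):
        from flymap.core import rucuca_map

        defaults = dict(marker_map=rucuca_map(), true_locus_cm=42.3, n_males=113, seed=0)
        defaults.update(kw)
        return ExperimentSpec(**defaults)

    def test_partition_property(self):
        """Per marker, parental + recombinant = number of known-state males."""
        from flymap.linkage import classify_pair

        males = simulate_mapping_experiment(self._spec(seed=4))
        known = (males["locus_state"] != "unknown").sum()
        for m in ("ru", "th", "ca"):
            pc = classify_pair(males, m)
            assert pc.n == known
            assert pc.n + pc.excluded == len(males)

    def test_locus_state_faithful_without_misclassification(self):
        males = simulate_mapping_experiment(
            self._spec(n_testcross_progeny=400, seed=5)
        )
        called = males[males["locus_state"] != "unknown"]
        assert (called["locus_state"] == called["locus_true"]).all()

    def test_misclassification_flips_some_states(self):
        males = simulate_mapping_experiment(
            self._spec(misclassification_rate=0.3, n_testcross_progeny=400, seed=6)
        )
        called = males[males["locus_state"] != "unknown"]
        frac = (called["locus_state"] != called["locus_true"]).mean()
        assert 0.15 < frac < 0.45

    def test_rf_to_nearest_marker_small(self):
        """Truth at 42.3 cM: RF to thread (43.2 cM) is < 5% in >= 95% of seeds."""
        from flymap.linkage import classify_pair, estimate_rf

        hits = 0
        n_rep = 100
        for s in range(n_rep):
            males = simulate_mapping_experiment(self._spec(seed=100 + s))
            hits += estimate_rf(classify_pair(males, "th")).rf < 5.0
        assert hits / n_rep >= 0.95

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            self._spec(misclassification_rate=0.7)
        with pytest.raises(ValueError):
            self._spec(true_locus_cm=500.0)


class TestDeficiencyPanel:
    def _spec(self, **kw):
        defaults = dict(
            true_locus_band=parse_cytoband("71F4"),
            n_deficiencies=30,
            div_lo=70,
            div_hi=74,
            max_subband=4,
            seed=0,
        )
        defaults.update(kw)
        return DeficiencyPanelSpec(**defaults)

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_free_panel_solves_to_truth(self, seed):
        panel = simulate_deficiency_panel(self._spec(seed=seed))
        region = solve_region(panel, max_subband=4)
        assert any(f.contains(parse_cytoband("71F4")) for f in region.fragments)

    def test_region_width_non_increasing_as_panel_grows(self):
        """More deficiencies can only sharpen (never widen) the region."""

        lattice = band_lattice("3L", 70, 74, 4)

        def width(region):
            return sum(1 for f in region.fragments for b in lattice if f.contains(b))

        for seed in range(10):
            panel = simulate_deficiency_panel(self._spec(n_deficiencies=50, seed=seed))
            prev = None
            for k in range(5, len(panel) + 1, 5):
                sub = panel[:k]
                if not any(d.outcome == "fails" for d in sub):
                    continue
                w = width(solve_region(sub, max_subband=4))
                if prev is not None:
                    assert w <= prev
                prev = w

    def test_always_contains_a_failing_deficiency(self):
        panel = simulate_deficiency_panel(self._spec(n_deficiencies=3, seed=1))
        assert any(d.outcome == "fails" for d in panel)

    def test_noise_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            self._spec(noise_rate=0.5)


class TestTilingPCR:
    GENE = GenomicInterval("3L", 15811576, 15820204)

    def test_no_insertion_all_wildtype(self):
        panel = simulate_tiling_pcr(TilingSpec(gene_interval=self.GENE))
        assert all(a.outcome == "amplified" for a in panel)
        assert all(a.observed_size == a.interval.length for a in panel)

    def test_large_insertion_fails_exactly_spanning_amplicons(self):
        site = 15815000
        spec = TilingSpec(
            gene_interval=self.GENE,
            insertion_site=site,
            insertion_size=7500,
            max_amplifiable=3000,
        )
        panel = simulate_tiling_pcr(spec)
        failed = {a.id for a in panel if a.outcome == "failed"}
        spanning = {a.id for a in panel if a.interval.contains_point(site)}
        assert failed == spanning and failed

    def test_small_insertion_size_shift_reported(self):
        site = 15815000
        spec = TilingSpec(
            gene_interval=self.GENE,
            insertion_site=site,
            insertion_size=800,
            max_amplifiable=3000,
        )
        panel = simulate_tiling_pcr(spec)
        shifted = [a for a in panel if a.interval.contains_point(site)]
        assert all(a.outcome == "amplified" for a in shifted)
        assert all(a.observed_size == a.interval.length + 800 for a in shifted)

    def test_tiling_covers_gene_contiguously(self):
        panel = simulate_tiling_pcr(TilingSpec(gene_interval=self.GENE))
        assert panel[0].interval.start == self.GENE.start
        assert panel[-1].interval.end == self.GENE.end
        for a, b in zip(panel, panel[1:]):
            assert b.interval.start <= a.interval.end + 1

    @pytest.mark.parametrize("seed", range(10))
    def test_lesion_finder_contains_insertion_site(self, seed):
        rng = np.random.default_rng(seed)
        site = int(rng.integers(self.GENE.start, self.GENE.end + 1))
        spec = TilingSpec(
            gene_interval=self.GENE,
            insertion_site=site,
            insertion_size=7500,
            seed=seed,
        )
        res = find_lesion_interval(simulate_tiling_pcr(spec))
        assert res.interval.contains_point(site)


class TestStageSurvival:
    PROPS = {"mut": 0.25, "het": 0.5, "bal": 0.25}

    def test_full_survival_no_attrition(self):
        surv = {c: [1.0, 1.0] for c in self.PROPS}
        tab = simulate_stage_survival(self.PROPS, surv, 1000, seed=0)
        assert (tab.iloc[:, 0] == tab.iloc[:, -1]).all()

    def test_lethal_class_never_hatches(self):
        surv = {"mut": [1.0], "het": [1.0], "bal": [0.0]}
        tab = simulate_stage_survival(self.PROPS, surv, 1000, seed=1, stages=["hatched"])
        assert tab.loc["bal", "hatched"] == 0

    def test_counts_non_increasing(self):
        surv = {c: [0.9, 0.7, 0.5] for c in self.PROPS}
        tab = simulate_stage_survival(self.PROPS, surv, 2000, seed=2)
        assert (tab.diff(axis=1).iloc[:, 1:].values <= 0).all()

    def test_proportions_match_binomial_oracle(self):
        """Observed stage survival within 3 binomial SE of the model."""
        n = 5000
        surv = {"mut": [0.6], "het": [0.9], "bal": [0.0]}
        tab = simulate_stage_survival(self.PROPS, surv, n, seed=3, stages=["hatched"])
        for c, p in (("mut", 0.6), ("het", 0.9)):
            n_c = tab.loc[c, "fertilized"]
            obs = tab.loc[c, "hatched"] / n_c
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n_c)

    def test_bit_reproducible(self):
        surv = {c: [0.8] for c in self.PROPS}
        a = simulate_stage_survival(self.PROPS, surv, 500, seed=9)
        b = simulate_stage_survival(self.PROPS, surv, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError):
            simulate_stage_survival({"a": 0.5, "b": 0.2}, {"a": [1.0], "b": [1.0]}, 10, seed=0)
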