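"""Pipeline orchestration: stage runners, configuration and JSON reports.

Each stage is a plain library function over the module APIs so tests and the
command line share one code path.  ``run_pipeline`` executes the stages named
in the config, writes one JSON per stage plus a human-readable summary, and
stamps every report with the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from .complementation import check_allelism, solve_region
from .core import MapError, MarkerMap, load_marker_map, rucuca_map
from .linkage import classify_pair, estimate_rf, format_rf, place_locus, pool_counts
from .molecular import find_lesion_interval
from .simulate import CrossoverModel, ExperimentSpec, simulate_mapping_experiment
from .viability import RatioModel, expected_classes, goodness_of_fit, stage_proportion

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_map_rf",
    "stage_place",
    "stage_complementation",
    "stage_tiling",
    "stage_viability",
]


@dataclasses.dataclass
class PipelineConfig:
    """Paths, method switches and the seed for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    stages: list[str] = dataclasses.field(default_factory=list)
    # inputs (TSV paths); a missing optional path disables its stage checks
    marker_map: str | None = None
    scored_males: str | None = None
    pair_counts: str | None = None
    deficiency_panel: str | None = None
    allele_tests: str | None = None
    gene_annotation: str | None = None
    amplicons: str | None = None
    stage_counts: str | None = None
    ratio_model: str | None = None
    # method switches
    ci_level: float = 0.95
    placement_method: str = "flank_subtraction"
    map_function: str = "identity"
    adjacency_radius: int = 1
    size_tolerance: float = 0.10
    # simulate-stage parameters
    true_locus_cm: float = 42.3
    n_males: int = 113
    n_testcross_progeny: int = 40

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        for name in (
            "marker_map",
            "scored_males",
            "pair_counts",
            "deficiency_panel",
            "allele_tests",
            "gene_annotation",
            "amplicons",
            "stage_counts",
            "ratio_model",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise MapError(f"config input {name} does not exist: {path}")


def _marker_map(config: PipelineConfig) -> MarkerMap:
    if config.marker_map:
        return load_marker_map(config.marker_map)
    return rucuca_map()


def stage_simulate(config: PipelineConfig) -> dict:
    mmap = _marker_map(config)
    spec = ExperimentSpec(
        marker_map=mmap,
        true_locus_cm=config.true_locus_cm,
        n_males=config.n_males,
        n_testcross_progeny=config.n_testcross_progeny,
        model=CrossoverModel(),
        seed=config.seed,
    )
    males = simulate_mapping_experiment(spec)
    out = Path(config.out_dir) / "scored_males.tsv"
    fio.write_scored_males(males, out)
    return {
        "n_males": int(len(males)),
        "true_locus_cm": config.true_locus_cm,
        "output": str(out),
        "locus_state_counts": males["locus_state"].value_counts().to_dict(),
    }


def stage_map_rf(config: PipelineConfig) -> dict:
    mmap = _marker_map(config)
    per_marker = {}
    excluded = 0
    if config.scored_males:
        males = fio.read_scored_males(config.scored_males)
        for m in mmap.names:
            if m not in males.columns:
                continue
            pc = classify_pair(males, m)
            excluded = pc.excluded
            est = estimate_rf(pc, config.ci_level)
            per_marker[m] = {
                "parental": pc.parental,
                "recombinant": pc.recombinant,
                "n": pc.n,
                "rf": est.rf,
                "rf_display": format_rf(est.rf),
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
    elif config.pair_counts:
        counts = fio.read_pair_counts(config.pair_counts)
        by_marker: dict[str, list] = {}
        for c in counts:
            by_marker.setdefault(c.marker, []).append(c)
        for m, reps in by_marker.items():
            pooled = pool_counts(reps)
            est = estimate_rf(pooled, config.ci_level)
            per_marker[m] = {
                "parental": pooled.parental,
                "recombinant": pooled.recombinant,
                "n": pooled.n,
                "rf": est.rf,
                "rf_display": format_rf(est.rf),
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
    else:
        raise MapError("map-rf stage needs scored_males or pair_counts input")
    return {"per_marker": per_marker, "excluded_males": excluded}


def stage_place(config: PipelineConfig, rf_report: dict | None = None) -> dict:
    from .linkage import RFEstimate

    if rf_report is None:
        rf_report = stage_map_rf(config)
    mmap = _marker_map(config)
    estimates = {
        m: RFEstimate(m, v["rf"], v["ci_low"], v["ci_high"], v["n"])
        for m, v in rf_report["per_marker"].items()
    }
    placement = place_locus(
        estimates,
        mmap,
        method=config.placement_method,
        map_function=config.map_function,
        rng=np.random.default_rng(config.seed),
    )
    return {
        "method": placement.method,
        "side": placement.side,
        "anchor": placement.anchor,
        "bounds_cm": list(placement.bounds),
        "ci_bounds_cm": list(placement.ci_bounds),
        "markers": list(placement.markers),
        "point_cm": placement.point,
        "note": placement.note,
    }


def stage_complementation(config: PipelineConfig) -> dict:
    if not config.deficiency_panel:
        raise MapError("complementation stage needs a deficiency_panel input")
    panel = fio.read_deficiency_panel(config.deficiency_panel)
    region = solve_region(panel)
    report = {
        "region": str(region.interval),
        "fragments": [str(f) for f in region.fragments],
        "supporting": list(region.supporting),
        "excluding": list(region.excluding),
    }
    if config.allele_tests and config.gene_annotation:
        tests = fio.read_allele_tests(config.allele_tests)
        annotation = fio.read_gene_annotation(config.gene_annotation)
        report["allelism"] = check_allelism(
            region, tests, annotation, config.adjacency_radius
        )
    return report


def stage_tiling(config: PipelineConfig) -> dict:
    if not config.amplicons:
        raise MapError("tiling stage needs an amplicons input")
    panel = fio.read_amplicons(config.amplicons)
    res = find_lesion_interval(panel, config.size_tolerance)
    return {
        "status": res.status,
        "interval": str(res.interval) if res.interval else None,
        "interval_bp": res.interval.length if res.interval else None,
        "clusters": [str(c) for c in res.clusters],
        "anomalous_amplicons": list(res.anomalous),
    }


def stage_viability(config: PipelineConfig) -> dict:
    if not config.stage_counts:
        raise MapError("viability stage needs a stage_counts input")
    wide = fio.read_stage_counts(config.stage_counts)
    stages = list(wide.columns)
    report: dict = {"stages": stages, "per_stage": {}}
    for prev, cur in zip(stages, stages[1:]):
        report["per_stage"][cur] = {
            str(c): stage_proportion(int(wide.loc[c, cur]), int(wide.loc[c, prev]))
            for c in wide.index
            if wide.loc[c, prev] > 0
        }
    if config.ratio_model:
        spec = json.loads(Path(config.ratio_model).read_text())
        model = RatioModel(
            proportions=spec["proportions"],
            survival=spec["survival"],
            stages=spec.get("stages", stages[1:]),
        )
        gof = {}
        for j, stage in enumerate(model.stages):
            if stage not in wide.columns:
                continue
            observed = wide[stage]
            live = observed[observed.index.isin(model.proportions)]
            exp = expected_classes(model, int(live.sum()), j)
            exp_pos = {c: v for c, v in exp.items() if v > 0}
            obs_pos = {c: int(live.get(c, 0)) for c in exp_pos}
            if len(exp_pos) < 2:
                continue
            res = goodness_of_fit(obs_pos, exp_pos)
            gof[stage] = {
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "method": res.method,
            }
        report["goodness_of_fit"] = gof
    return report


_STAGES = {
    "simulate": stage_simulate,
    "map-rf": stage_map_rf,
    "place": stage_place,
    "complementation": stage_complementation,
    "tiling": stage_tiling,
    "viability": stage_viability,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write per-stage JSON + a summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed, "config_hash": config.digest()}
    report: dict = {"meta": meta}
    rf_report = None
    for stage in config.stages or ["map-rf", "place"]:
        if stage not in _STAGES:
            raise MapError(f"unknown stage {stage!r}")
        try:
            if stage == "place":
                result = stage_place(config, rf_report)
            else:
                result = _STAGES[stage](config)
        except MapError as err:
            raise type(err)(f"stage {stage}: {err}") from err
        if stage == "map-rf":
            rf_report = result
        report[stage] = result
        fio.write_json({**meta, stage: result}, out_dir / f"{stage.replace('-', '_')}.json")

    lines = [f"flymap {__version__}  seed={config.seed}  config={meta['config_hash']}"]
    for stage, result in report.items():
        if stage == "meta":
            continue
        lines.append(f"[{stage}] {json.dumps(result, sort_keys=True, default=str)[:400]}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    fio.write_json(report, out_dir / "report.json")
    return report
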