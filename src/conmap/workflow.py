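"""End-to-end orchestration: QC -> two-point -> grouping -> ordering -> maps.

Every run can write a JSON-lines log of parameters, filter counts and final
likelihoods; all randomness flows from a single top-level seed with stage
seeds derived deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PopulationDataset, write_map_tables
from .qc import filter_markers, segregation_test
from .twopoint import twopoint_matrix
from .ordering import group_markers, order_seq, ripple, LinkageGroup
from .hmm import GeneticMap, em_fit, em_fit_joint
from .composite import build_composite, CompositeResult
from .simulate import SimConfig, make_truth, simulate_connected

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_single_map", "run_composite",
           "run_simulation_study", "order_recovery_study"]


@dataclass
class RunConfig:
    """Thresholds and knobs for a mapping run (defaults as configured
    throughout: grouping LOD 7.5, max rf 0.35, 25% missing-data cap,
    genotyping-error probability 0.05, seed subset of 6, ripple window 4)."""

    lod_min: float = 7.5
    rf_max: float = 0.35
    max_missing: float = 0.25
    epsilon: float = 0.05
    alpha: float = 0.05
    seed_size: int = 6
    window: int = 4
    ambiguity_lod: float = 3.0
    drop_distorted: bool = False
    score_iters: int = 20
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.rf_max <= 0.5 and 0 <= self.max_missing <= 1
                and 0 <= self.epsilon < 0.5 and 0 < self.alpha < 1):
            raise ValueError("threshold outside its documented domain")


def load_config(path) -> dict:
    """Parse a plain ``key = value`` config file into RunConfig kwargs.

    Unknown keys raise; values are coerced to the dataclass field types.
    Command-line flags are meant to override file values.
    """
    fields = {f.name: f.type for f in RunConfig.__dataclass_fields__.values()}
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in ("out_dir",):
            out[key] = raw
        elif key in ("drop_distorted",):
            out[key] = raw.lower() in ("1", "true", "yes")
        elif key in ("seed", "seed_size", "window", "score_iters"):
            out[key] = int(raw)
        else:
            out[key] = float(raw)
    return out


class _RunLog:
    def __init__(self, out_dir: str | None):
        self.path = (Path(out_dir) / "run_log.jsonl") if out_dir else None
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def __call__(self, stage: str, **info) -> None:
        record = {"stage": stage, **info}
        log.info("%s: %s", stage, info)
        if self.path:
            with self.path.open("a") as fh:
                fh.write(json.dumps(record) + "\n")


def _qc_stage(dataset: PopulationDataset, config: RunConfig, runlog,
              ) -> PopulationDataset:
    if dataset.n_markers == 0 or dataset.n_progeny == 0:
        raise ValueError(f"QC: dataset {dataset.population_id} is empty")
    filtered, report = filter_markers(dataset, config.max_missing)
    seg = segregation_test(filtered, config.alpha)
    distorted = [r.marker_name for r in seg if r.distorted]
    if config.drop_distorted and distorted:
        keep = [nm for nm in filtered.marker_names if nm not in set(distorted)]
        filtered = filtered.subset(keep)
    runlog("qc", population=dataset.population_id,
           n_input=dataset.n_markers, n_after_missing=len(report) and
           dataset.n_markers - len(report) or filtered.n_markers,
           n_removed_missing=len(report), n_distorted=len(distorted),
           dropped_distorted=config.drop_distorted)
    return filtered


def _map_groups(dataset: PopulationDataset, config: RunConfig, runlog
                ) -> tuple[list[GeneticMap], list[LinkageGroup]]:
    tp = twopoint_matrix(dataset)
    groups = group_markers(tp, dataset.marker_names,
                           lod_min=config.lod_min, rf_max=config.rf_max)
    runlog("grouping", population=dataset.population_id,
           n_groups=sum(1 for g in groups if g.size > 1),
           n_singletons=sum(1 for g in groups if g.size == 1))
    maps: list[GeneticMap] = []
    for grp in groups:
        if grp.size < 2:
            continue
        if grp.size >= 3:
            _, gm = order_seq(grp, dataset, seed_size=config.seed_size,
                              epsilon=config.epsilon,
                              ambiguity_lod=config.ambiguity_lod,
                              tp_matrix=tp, score_iters=config.score_iters)
            gm = ripple(gm, dataset, window=config.window,
                        epsilon=config.epsilon,
                        score_iters=config.score_iters)
        else:
            gm = em_fit(grp.marker_names, dataset, epsilon=config.epsilon)
        maps.append(gm)
        runlog("order", population=dataset.population_id,
               group=grp.group_id, n_markers=gm.n_markers,
               length_cM=round(gm.length_cm, 3),
               loglik=round(gm.loglik, 3))
    return maps, groups


def _maps_table(maps: list[GeneticMap], dataset: PopulationDataset
                ) -> pd.DataFrame:
    rows = []
    for gid, gm in enumerate(maps, start=1):
        for nm, p in zip(gm.marker_names, gm.positions_cm):
            rows.append({
                "linkage_group": gid, "marker_name": nm,
                "position_cM": round(float(p), 4),
                "cross_type": dataset.marker(nm).cross_type.value,
                "provenance": dataset.population_id,
            })
    return pd.DataFrame(rows, columns=["linkage_group", "marker_name",
                                       "position_cM", "cross_type",
                                       "provenance"])


def run_single_map(dataset: PopulationDataset, config: RunConfig | None = None
                   ) -> dict:
    """QC, two-point analysis, grouping, ordering, multipoint maps."""
    config = config or RunConfig()
    runlog = _RunLog(config.out_dir)
    runlog("config", **{k: v for k, v in asdict(config).items()})
    filtered = _qc_stage(dataset, config, runlog)
    maps, groups = _map_groups(filtered, config, runlog)
    table = _maps_table(maps, filtered)
    if config.out_dir:
        write_map_tables(table, config.out_dir)
    return {"maps": maps, "groups": groups, "table": table,
            "dataset": filtered}


def run_composite(ds1: PopulationDataset, ds2: PopulationDataset,
                  config: RunConfig | None = None) -> dict:
    """Per-population maps, then the composite construction."""
    config = config or RunConfig()
    if ds1.female_id != ds2.female_id:
        raise ValueError("composite: the two populations must share the "
                         "female parent")
    runlog = _RunLog(config.out_dir)
    runlog("config", **{k: v for k, v in asdict(config).items()})
    f1 = _qc_stage(ds1, config, runlog)
    f2 = _qc_stage(ds2, config, runlog)
    shared = [nm for nm in f1.marker_names if nm in f2]
    if not shared:
        raise ValueError("composite: no shared markers between populations")
    maps1, _ = _map_groups(f1, config, runlog)
    maps2, _ = _map_groups(f2, config, runlog)
    result = build_composite(f1, f2, maps1, maps2, epsilon=config.epsilon,
                             window=config.window,
                             score_iters=config.score_iters)
    runlog("composite",
           n_groups=len(result.composite_groups),
           n_shared_framework=sum(cm.framework.n_markers
                                  for cm in result.composite_groups),
           n_markers=sum(cm.n_markers for cm in result.composite_groups))
    if config.out_dir:
        table = result.map_table()
        table["cross_type"] = [
            (f1.marker(nm).cross_type.value if nm in f1
             else f2.marker(nm).cross_type.value)
            for nm in table["marker_name"]]
        write_map_tables(table, config.out_dir)
        result.summary().to_csv(Path(config.out_dir) / "composite_summary.tsv",
                                sep="\t", index=False)
    return {"result": result, "maps1": maps1, "maps2": maps2,
            "datasets": (f1, f2)}


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_simulation_study(
    n_replicates: int = 20,
    n_markers: int = 15,
    rf_range: tuple[float, float] = (0.01, 0.2),
    n1: int = 160,
    n2: int = 184,
    epsilon: float = 0.05,
    missing_rate: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Recombination-fraction recovery of joint vs single-population EM.

    Each replicate simulates one group of shared markers, fits the joint
    two-population EM and each single-population EM on the true order, and
    records the per-interval estimation errors.  Returns a long-format table
    (replicate, interval, r_true, r_joint, r_pop1, r_pop2); empty for zero
    replicates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        cfg = SimConfig(n1=n1, n2=n2, epsilon=epsilon,
                        missing_rate=missing_rate, seed=_child_seed(rng))
        truth = make_truth(n_markers, cfg, rf_range=rf_range,
                           rng=np.random.default_rng(_child_seed(rng)))
        ds1, ds2 = simulate_connected(truth, cfg)
        order = truth.marker_names
        gm_joint = em_fit_joint(order, ds1, ds2, epsilon=epsilon)
        gm1 = em_fit(order, ds1, epsilon=epsilon)
        gm2 = em_fit(order, ds2, epsilon=epsilon)
        for j in range(n_markers - 1):
            rows.append({
                "replicate": rep, "interval": j,
                "r_true": truth.rf[j],
                "r_joint": gm_joint.rf[j],
                "r_pop1": gm1.rf[j],
                "r_pop2": gm2.rf[j],
            })
    return pd.DataFrame(rows, columns=["replicate", "interval", "r_true",
                                       "r_joint", "r_pop1", "r_pop2"])


def rmse_by_interval(study: pd.DataFrame) -> pd.DataFrame:
    """Interval-wise RMSE of each estimator from a recovery study table."""
    def _rmse(err):
        return float(np.sqrt(np.mean(np.square(err))))
    out = []
    for j, grp in study.groupby("interval"):
        out.append({
            "interval": j,
            "rmse_joint": _rmse(grp["r_joint"] - grp["r_true"]),
            "rmse_pop1": _rmse(grp["r_pop1"] - grp["r_true"]),
            "rmse_pop2": _rmse(grp["r_pop2"] - grp["r_true"]),
        })
    return pd.DataFrame(out)


def order_recovery_study(
    n_replicates: int = 50,
    n_markers: int = 12,
    spacing_cm: tuple[float, float] = (5.0, 15.0),
    n1: int = 160,
    n2: int = 184,
    epsilon: float = 0.05,
    missing_rate: float = 0.10,
    seed: int = 0,
    seed_size: int = 6,
    window: int = 4,
    score_iters: int = 15,
) -> pd.DataFrame:
    """Composite-framework order recovery on simulated connected populations.

    Each replicate simulates one group, builds both individual maps with the
    seeded order search plus ripple, constructs the joint framework with
    conflict resolution, and records whether the final framework order equals
    the simulated truth or its mirror.
    """
    from .markers import kosambi_inverse
    from .composite import build_framework, resolve_conflicts

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        cfg = SimConfig(n1=n1, n2=n2, epsilon=epsilon,
                        missing_rate=missing_rate, seed=_child_seed(rng))
        spacing = np.random.default_rng(_child_seed(rng)).uniform(
            spacing_cm[0], spacing_cm[1], size=n_markers - 1)
        truth = make_truth(n_markers, cfg,
                           rng=np.random.default_rng(_child_seed(rng)))
        truth.rf = kosambi_inverse(spacing)
        ds1, ds2 = simulate_connected(truth, cfg)
        maps = []
        for ds in (ds1, ds2):
            tp = twopoint_matrix(ds)
            _, gm = order_seq(ds.marker_names, ds, seed_size=seed_size,
                              epsilon=epsilon, tp_matrix=tp,
                              score_iters=score_iters)
            gm = ripple(gm, ds, window=window, epsilon=epsilon,
                        score_iters=score_iters)
            maps.append(gm)
        try:
            fw = build_framework(maps[0], maps[1], ds1, ds2, epsilon=epsilon)
        except ValueError:
            # too few markers placed in both individual maps: no framework,
            # counted as a failed recovery
            rows.append({"replicate": rep, "n_framework": 0,
                         "order_recovered": False})
            continue
        fw = resolve_conflicts(fw, maps[0], maps[1], ds1, ds2,
                               epsilon=epsilon, window=window,
                               score_iters=score_iters)
        truth_order = [nm for nm in truth.marker_names
                       if nm in set(fw.marker_names)]
        got = fw.marker_names
        rows.append({
            "replicate": rep,
            "n_framework": len(got),
            "order_recovered": got == truth_order or got == truth_order[::-1],
        })
    return pd.DataFrame(rows, columns=["replicate", "n_framework",
                                       "order_recovered"])
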