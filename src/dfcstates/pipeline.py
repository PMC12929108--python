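"""End-to-end orchestration: simulate/load -> windows -> states -> metrics -> stats.

One :class:`PipelineConfig` drives the full analysis with a single master
seed fanned out deterministically (via ``numpy.random.SeedSequence.spawn``)
into independent per-stage streams, so any run is bit-reproducible. Stage
outputs are persisted as delimited tables and JSON reports under the output
directory; the run report records seeds, timings and validity flags.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, graphs, stats, synthetic, temporal, windows

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline", "load_roi_tables"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Defaults mirror the standard protocol: window width 30 TR / step 1 TR,
    elbow selection over K = 2..8, sparsity sweep 0.10-0.40 step 0.01,
    5,000 permutations, NBS edge alpha 0.001 / component alpha 0.05 /
    1,000 iterations, FDR q = 0.05, and >= 10 pooled windows per state for
    validity.
    """

    outdir: str = "dfcstates_run"
    mode: str = "synthetic"  # "synthetic" | "roi-tables"
    manifest: Optional[str] = None  # roi-tables mode
    seed: int = 0
    # synthetic cohort
    n_per_group: tuple[int, int, int] = (4, 4, 4)
    n_timepoints: int = 230
    n_rois: int = 30
    # windowing
    window_width: int = 30
    window_step: int = 1
    detrend: bool = False
    repetition_time: float = 2.64
    # clustering
    k: Optional[int] = None  # fixed K; None selects by elbow
    k_min: int = 2
    k_max: int = 8
    n_init: int = 20
    max_iter: int = 300
    min_state_windows: int = 10
    # graph sweep
    sparsity_low: float = 0.10
    sparsity_high: float = 0.40
    sparsity_step: float = 0.01
    include_small_world: bool = False
    small_world_nulls: int = 20
    # statistics
    n_perm: int = 5000
    fdr_q: float = 0.05
    run_nbs: bool = True
    nbs_edge_alpha: float = 0.001
    nbs_comp_alpha: float = 0.05
    nbs_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "n_per_group" in raw:
            raw["n_per_group"] = tuple(raw["n_per_group"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["n_per_group"] = list(d["n_per_group"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def sparsities(self) -> np.ndarray:
        return graphs.default_sparsity_sweep(
            self.sparsity_low, self.sparsity_high, self.sparsity_step
        )


@dataclass
class RunReport:
    config: dict
    seeds: dict
    stage_seconds: dict = field(default_factory=dict)
    selected_k: Optional[int] = None
    elbow_costs: Optional[dict] = None
    state_window_counts: Optional[list] = None
    state_validity: Optional[dict] = None
    outputs: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        # timing is environment-dependent; keep it out of the reproducible core
        timing = payload.pop("stage_seconds")
        Path(path).write_text(
            json.dumps({"report": payload, "stage_seconds": timing}, indent=2, sort_keys=True)
        )


def load_roi_tables(manifest_path: str | Path, repetition_time: float = 2.64):
    """Load per-subject ROI tables listed in a cohort manifest.

    The manifest needs columns subject_id, group, age, gender, path; every
    series must be finite with one shared ROI-label header (same order).
    Returns ``(list of ROITimeSeries, manifest frame)``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep=None, engine="python")
    required = {"subject_id", "group", "age", "gender", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise windows.InputError(f"manifest missing columns: {sorted(missing)}")
    series_list = []
    labels: Optional[list[str]] = None
    offenders = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        ts = windows.read_roi_table(p, subject_id=row["subject_id"],
                                    repetition_time=repetition_time)
        if labels is None:
            labels = ts.roi_labels
        elif ts.roi_labels != labels:
            offenders.append(str(row["subject_id"]))
        series_list.append(ts)
    if offenders:
        raise windows.InputError(
            f"ROI labels/order differ from the first subject for: {offenders}"
        )
    return series_list, manifest


def _contrasts(groups: pd.Series) -> list[tuple[str, str]]:
    return list(combinations(sorted(groups.unique()), 2))


def _usable_covariates(covs: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Drop covariate columns that are constant within the contrast."""
    keep = covs.loc[:, covs.nunique() > 1]
    if keep.shape[1] < covs.shape[1]:
        dropped = sorted(set(covs.columns) - set(keep.columns))
        logger.info("dropping constant covariate column(s) %s for this contrast", dropped)
    return keep if keep.shape[1] else None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; raises :class:`PipelineError` on stage failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    sim_ss, cluster_ss, graph_ss, stats_ss = master.spawn(4)
    report = RunReport(
        config=dataclasses.asdict(config),
        seeds={
            "master": config.seed,
            "stage_spawn_order": ["simulate", "cluster", "graphs", "stats"],
        },
    )
    spec = windows.WindowSpec(width=config.window_width, step=config.window_step)

    # ---- stage: input -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.mode == "synthetic":
            cohort = synthetic.simulate_cohort(
                synthetic.default_latent_model(config.n_rois),
                synthetic.default_group_specs(config.n_per_group, config.n_rois),
                n_timepoints=config.n_timepoints,
                seed=int(sim_ss.generate_state(1)[0] % (2**31)),
            )
            synthetic.write_cohort(cohort, outdir / "cohort")
            manifest = cohort.manifest_frame()
            series_list = [
                windows.ROITimeSeries(
                    s.subject_id, s.series, list(cohort.roi_labels),
                    config.repetition_time,
                )
                for s in cohort.subjects
            ]
        elif config.mode == "roi-tables":
            if not config.manifest:
                raise PipelineError("input stage: roi-tables mode needs a manifest path")
            series_list, manifest = load_roi_tables(
                config.manifest, config.repetition_time
            )
        else:
            raise PipelineError(f"input stage: unknown mode {config.mode!r}")
    except (synthetic.ConfigurationError, windows.InputError) as exc:
        raise PipelineError(f"input stage: {exc}") from exc
    report.stage_seconds["input"] = time.perf_counter() - t0
    report.outputs["manifest"] = str(outdir / "cohort" / "manifest.tsv")

    # ---- stage: windows ---------------------------------------------------
    t0 = time.perf_counter()
    windir = outdir / "windows"
    windir.mkdir(exist_ok=True)
    z_list = []
    try:
        for ts in series_list:
            if config.detrend:
                ts = ts.detrended()
            wfc = windows.sliding_window_fc(ts, spec)
            zs = windows.fisher_z_series(wfc)
            z_list.append(zs)
            windows.save_z_series(zs, windir, spec)
            var = windows.dfc_variability(zs)
            pd.DataFrame(var.sd_matrix, columns=ts.roi_labels).to_csv(
                windir / f"{ts.subject_id}_variability.tsv",
                sep="\t", index=False, float_format="%.8g",
            )
    except windows.InputError as exc:
        raise PipelineError(f"windowing stage: {exc}") from exc
    report.stage_seconds["windows"] = time.perf_counter() - t0

    # ---- stage: clustering ------------------------------------------------
    t0 = time.perf_counter()
    cdir = outdir / "clustering"
    cdir.mkdir(exist_ok=True)
    features = clustering.build_feature_matrix(z_list)
    if config.k is not None:
        partition = clustering.kmeans_manhattan(
            features, config.k, n_init=config.n_init,
            max_iter=config.max_iter, seed=cluster_ss,
        )
        selected_k = config.k
        elbow = None
    else:
        elbow = clustering.select_k_elbow(
            features,
            k_range=range(config.k_min, config.k_max + 1),
            n_init=config.n_init,
            max_iter=config.max_iter,
            seed=cluster_ss,
            keep_partitions=True,
        )
        selected_k = elbow.selected_k
        partition = elbow.partitions[selected_k]
        pd.DataFrame({"k": elbow.k_values, "cost": elbow.costs}).to_csv(
            cdir / "elbow.tsv", sep="\t", index=False, float_format="%.8g"
        )
    validity = clustering.validate_states(partition, config.min_state_windows)
    counts = partition.state_counts()
    report.selected_k = int(selected_k)
    report.state_window_counts = counts.tolist()
    report.state_validity = {str(k): bool(v) for k, v in validity.items()}
    if elbow is not None:
        report.elbow_costs = {
            str(k): float(c) for k, c in zip(elbow.k_values, elbow.costs)
        }
    pd.DataFrame(partition.centroids).to_csv(
        cdir / "centroids.tsv", sep="\t", index=False, float_format="%.8g"
    )
    pd.DataFrame(
        {
            "subject_id": [s for s, _ in partition.row_index],
            "window": [w for _, w in partition.row_index],
            "state": partition.labels,
        }
    ).to_csv(cdir / "labels.tsv", sep="\t", index=False)
    (cdir / "clustering.json").write_text(
        json.dumps(
            {
                "selected_k": int(selected_k),
                "total_cost": partition.total_cost,
                "n_init": config.n_init,
                "state_window_counts": counts.tolist(),
                "validity": report.state_validity,
            },
            indent=2, sort_keys=True,
        )
    )
    report.stage_seconds["cluster"] = time.perf_counter() - t0
    if not all(validity.values()):
        bad = [s for s, ok in validity.items() if not ok]
        raise PipelineError(
            f"clustering stage: state(s) {bad} hold fewer than "
            f"{config.min_state_windows} windows; partition is not valid"
        )

    # ---- stage: temporal metrics -----------------------------------------
    t0 = time.perf_counter()
    tdir = outdir / "temporal"
    tdir.mkdir(exist_ok=True)
    timelines = temporal.timelines_from_labels(partition.labels, partition.row_index)
    temporal_table = temporal.temporal_metrics_table(
        timelines, selected_k, manifest=manifest,
        repetition_time=config.repetition_time,
    )
    temporal_table.to_csv(
        tdir / "temporal_metrics.tsv", sep="\t", index=False, float_format="%.8g"
    )
    report.outputs["temporal_metrics"] = str(tdir / "temporal_metrics.tsv")
    report.stage_seconds["temporal"] = time.perf_counter() - t0

    # ---- stage: graph metrics --------------------------------------------
    t0 = time.perf_counter()
    gdir = outdir / "graphs"
    gdir.mkdir(exist_ok=True)
    sparsities = config.sparsities()
    tl_by_sid = {tl.subject_id: tl for tl in timelines}
    global_auc_rows, nodal_auc_rows = [], []
    graph_seed_iter = iter(graph_ss.spawn(len(z_list) * selected_k))
    for zs in z_list:
        tl = tl_by_sid[zs.subject_id]
        for state in range(1, selected_k + 1):
            sseed = next(graph_seed_iter)
            net = graphs.state_network(zs, tl, state)
            if net is None:
                continue
            gdf, ndf = graphs.sweep_metrics(
                net.mean_z_matrix,
                sparsities,
                include_small_world=config.include_small_world,
                n_null=config.small_world_nulls,
                seed=sseed,
            )
            for metric in [c for c in gdf.columns if c != "sparsity"]:
                global_auc_rows.append(
                    {
                        "subject_id": zs.subject_id,
                        "state": state,
                        "metric": metric,
                        "auc": float(graphs.metric_auc(sparsities, gdf[metric].to_numpy())),
                        "n_windows_used": net.n_windows_used,
                    }
                )
            for metric in ("Ne", "Ncc", "Dc", "Bc"):
                wide = ndf.pivot(index="sparsity", columns="node", values=metric)
                aucs = graphs.metric_auc(sparsities, wide.to_numpy())
                for node, val in enumerate(np.atleast_1d(aucs)):
                    nodal_auc_rows.append(
                        {
                            "subject_id": zs.subject_id,
                            "state": state,
                            "metric": metric,
                            "node": node,
                            "auc": float(val),
                        }
                    )
    global_auc = pd.DataFrame(global_auc_rows)
    nodal_auc = pd.DataFrame(nodal_auc_rows)
    global_auc.to_csv(gdir / "global_auc.tsv", sep="\t", index=False, float_format="%.8g")
    nodal_auc.to_csv(gdir / "nodal_auc.tsv", sep="\t", index=False, float_format="%.8g")
    report.outputs["global_auc"] = str(gdir / "global_auc.tsv")
    report.outputs["nodal_auc"] = str(gdir / "nodal_auc.tsv")
    report.stage_seconds["graphs"] = time.perf_counter() - t0

    # ---- stage: group statistics -----------------------------------------
    t0 = time.perf_counter()
    sdir = outdir / "stats"
    sdir.mkdir(exist_ok=True)
    stat_children = stats_ss.spawn(3)
    temporal_stats = _temporal_group_stats(
        temporal_table, selected_k, config, stat_children[0]
    )
    temporal_stats.to_csv(
        sdir / "temporal_stats.tsv", sep="\t", index=False, float_format="%.8g"
    )
    nodal_stats = _nodal_group_stats(
        nodal_auc, manifest, selected_k, config, stat_children[1]
    )
    nodal_stats.to_csv(
        sdir / "nodal_stats.tsv", sep="\t", index=False, float_format="%.8g"
    )
    nbs_report: dict = {}
    if config.run_nbs:
        nbs_report = _nbs_group_stats(
            z_list, timelines, manifest, selected_k, config, stat_children[2]
        )
        (sdir / "nbs.json").write_text(json.dumps(nbs_report, indent=2, sort_keys=True))
    report.outputs["temporal_stats"] = str(sdir / "temporal_stats.tsv")
    report.outputs["nodal_stats"] = str(sdir / "nodal_stats.tsv")
    report.stage_seconds["stats"] = time.perf_counter() - t0

    # headline: per-group mean FW/MDT per state
    headline = {}
    for metric in ["FW", "MDT"]:
        for s in range(1, selected_k + 1):
            col = f"{metric}_{s}"
            headline[col] = {
                g: float(v) for g, v in
                temporal_table.groupby("group")[col].mean().items()
            }
    report.headline = headline
    report.to_json(outdir / "report.json")
    return report


def _temporal_group_stats(
    table: pd.DataFrame, k: int, config: PipelineConfig, seed: np.random.SeedSequence
) -> pd.DataFrame:
    """Pairwise permutation tests on FW/MDT/transitions, FDR per metric kind.

    FDR families follow the metric kind: all states x contrasts for FW, the
    same for MDT, and the contrasts alone for the transition count.
    """
    rows = []
    contrast_seeds = iter(seed.spawn(3 * (k + k + 1)))
    covs = table[["age", "gender"]]
    for kind, cols in (
        ("FW", [f"FW_{s}" for s in range(1, k + 1)]),
        ("MDT", [f"MDT_{s}" for s in range(1, k + 1)]),
        ("transitions", ["n_transitions"]),
    ):
        family_rows = []
        for col in cols:
            for ga, gb in _contrasts(table["group"]):
                mask = table["group"].isin([ga, gb]).to_numpy()
                res = stats.permutation_test(
                    table.loc[mask, col].to_numpy(),
                    table.loc[mask, "group"].to_numpy(),
                    _usable_covariates(covs[mask]),
                    n_perm=config.n_perm,
                    seed=next(contrast_seeds),
                )
                family_rows.append(
                    {
                        "metric": col,
                        "family": kind,
                        "contrast": f"{ga}_vs_{gb}",
                        "observed": res.observed_stat,
                        "p_raw": res.p_value,
                    }
                )
        fdr = stats.fdr_bh([r["p_raw"] for r in family_rows], q=config.fdr_q, family=kind)
        for r, adj, rej in zip(family_rows, fdr.adjusted_p, fdr.rejected):
            r["p_fdr"] = float(adj)
            r["significant"] = bool(rej)
        rows.extend(family_rows)
    return pd.DataFrame(rows)


def _nodal_group_stats(
    nodal_auc: pd.DataFrame,
    manifest: pd.DataFrame,
    k: int,
    config: PipelineConfig,
    seed: np.random.SeedSequence,
) -> pd.DataFrame:
    """Per-node permutation tests of metric AUCs; FDR across nodes.

    The family is the node set within each (metric, state, contrast);
    subjects who never visit a state are excluded from that state's tests,
    and a test is skipped when a group retains fewer than 2 subjects.
    """
    rows = []
    seeds = iter(seed.spawn(4 * k * 3))
    meta = manifest.set_index("subject_id")
    for metric in ("Ne", "Ncc", "Dc", "Bc"):
        for state in range(1, k + 1):
            sub = nodal_auc[(nodal_auc["metric"] == metric) & (nodal_auc["state"] == state)]
            if sub.empty:
                continue
            wide = sub.pivot(index="subject_id", columns="node", values="auc")
            for ga, gb in _contrasts(manifest["group"]):
                sids = [
                    s for s in wide.index if meta.loc[s, "group"] in (ga, gb)
                ]
                groups = meta.loc[sids, "group"].to_numpy()
                child = next(seeds)
                if min((groups == ga).sum(), (groups == gb).sum()) < 2:
                    logger.warning(
                        "skipping %s state %d %s vs %s: fewer than 2 subjects per group",
                        metric, state, ga, gb,
                    )
                    continue
                vals = wide.loc[sids].to_numpy()
                covs = _usable_covariates(meta.loc[sids, ["age", "gender"]])
                obs, p = stats.permutation_test_many(
                    vals, groups, covs, n_perm=config.n_perm, seed=child
                )
                fdr = stats.fdr_bh(p, q=config.fdr_q,
                                   family=f"{metric}_state{state}_{ga}_vs_{gb}")
                for node in range(vals.shape[1]):
                    rows.append(
                        {
                            "metric": metric,
                            "state": state,
                            "contrast": f"{ga}_vs_{gb}",
                            "node": node,
                            "observed": float(obs[node]),
                            "p_raw": float(p[node]),
                            "p_fdr": float(fdr.adjusted_p[node]),
                            "significant": bool(fdr.rejected[node]),
                        }
                    )
    return pd.DataFrame(rows)


def _nbs_group_stats(
    z_list, timelines, manifest: pd.DataFrame, k: int,
    config: PipelineConfig, seed: np.random.SeedSequence,
) -> dict:
    """NBS contrasts of per-state mean networks (edgewise, per state/contrast)."""
    meta = manifest.set_index("subject_id")
    tl_by_sid = {tl.subject_id: tl for tl in timelines}
    out: dict = {}
    seeds = iter(seed.spawn(k * 3))
    for state in range(1, k + 1):
        nets = {}
        for zs in z_list:
            net = graphs.state_network(zs, tl_by_sid[zs.subject_id], state)
            if net is not None:
                nets[zs.subject_id] = clustering.vectorize_fc(net.mean_z_matrix)
        for ga, gb in _contrasts(manifest["group"]):
            child = next(seeds)
            sids = [s for s in nets if meta.loc[s, "group"] in (ga, gb)]
            groups = meta.loc[sids, "group"].to_numpy()
            key = f"state{state}_{ga}_vs_{gb}"
            if min((groups == ga).sum(), (groups == gb).sum()) < 2:
                out[key] = {"skipped": "fewer than 2 subjects per group"}
                continue
            res = stats.nbs(
                np.vstack([nets[s] for s in sids]),
                groups,
                _usable_covariates(meta.loc[sids, ["age", "gender"]]),
                edge_alpha=config.nbs_edge_alpha,
                comp_alpha=config.nbs_comp_alpha,
                n_iter=config.nbs_iter,
                seed=child,
            )
            out[key] = {
                "n_suprathreshold_edges": len(res.suprathreshold_edges),
                "components": [
                    {
                        "n_edges": c["n_edges"],
                        "p_corrected": c["p_corrected"],
                        "nodes": [int(n) for n in c["nodes"]],
                    }
                    for c in res.components
                ],
            }
    return out
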