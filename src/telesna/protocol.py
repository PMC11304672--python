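"""End-to-end orchestration of the five-step robustness protocol.

Given telemetry (or a prebuilt network), run in order:

1. datastream-permutation null test of the global metrics,
2. node subsampling of the observed (and permuted) networks,
3. bootstrap confidence intervals for global metrics, CI width vs
   sample size, and split-half calibration,
4. partial-vs-full node-metric correlation (and regression),
5. bootstrap confidence intervals for node-level metrics,

writing tidy CSVs, figures and a machine-readable run manifest.  Step 1
is skipped automatically when the input is a prebuilt network (e.g.
observational data where associations are already known); steps 4-5
depend only on the network, not on steps 1-3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    Thresholds,
    build_network,
    read_edgelist_csv,
    read_graphml,
    write_edgelist_csv,
    write_graphml,
)
from .io import TelemetryDataset, read_telemetry, summarize_dataset
from .metrics import DEFAULT_GLOBAL_METRICS, NODE_METRICS, global_metrics, node_metrics
from .permutation import null_distribution, null_summary, null_values_table
from .resampling import (
    DEFAULT_LEVELS,
    bootstrap_global_ci,
    bootstrap_node_ci,
    ci_width_vs_samplesize,
    split_half_calibration,
    subsample_distribution,
)
from .stability import DEFAULT_LEVELS as CORR_LEVELS
from .stability import node_metric_correlation, node_metric_regression

logger = logging.getLogger(__name__)


@dataclass
class ProtocolConfig:
    """All knobs of the five-step protocol, YAML-serialisable."""

    input_path: str = ""
    input_format: str = "csv"  # csv | graphml | edgelist
    coordinate_mode: str = "projected"
    day_timezone: str = "UTC"
    spatial_threshold: float = 15.0
    temporal_threshold: float = 7.0
    matching: str = "greedy_one_to_one"
    window: str = "symmetric"
    min_denominator: int = 0
    global_metrics: list = field(default_factory=lambda: list(DEFAULT_GLOBAL_METRICS))
    node_metrics: list = field(default_factory=lambda: list(NODE_METRICS))
    n_perm: int = 1000
    levels: list = field(default_factory=lambda: list(DEFAULT_LEVELS))
    corr_levels: list = field(default_factory=lambda: list(CORR_LEVELS))
    n_rep: int = 100
    corr_n_rep: int = 10
    B: int = 1000
    conf: float = 0.95
    n_outer: int = 10
    ci_sizes: list | None = None
    split_trials: int = 50
    corr_method: str = "pearson"
    weighted_paths: bool = False
    dup_edge_rule: str = "always_draw"
    seed: int = 0
    output_dir: str = "telesna_report"
    make_plots: bool = True

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_rep", "corr_n_rep", "B", "n_outer", "split_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not all(0 < lv <= 1 for lv in list(self.levels) + list(self.corr_levels)):
            raise ValueError("subsampling levels must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ProtocolConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(s=self.spatial_threshold, t=self.temporal_threshold)


def load_input(cfg: ProtocolConfig) -> tuple[TelemetryDataset | None, nx.Graph]:
    """Load telemetry (building the network) or a prebuilt network."""
    if cfg.input_format == "csv":
        ds = read_telemetry(cfg.input_path, coordinate_mode=cfg.coordinate_mode,
                            day_timezone=cfg.day_timezone)
        net = build_network(ds, cfg.thresholds, matching=cfg.matching,
                            window=cfg.window, min_denominator=cfg.min_denominator)
        return ds, net
    if cfg.input_format == "graphml":
        return None, read_graphml(cfg.input_path)
    if cfg.input_format == "edgelist":
        return None, read_edgelist_csv(cfg.input_path)
    raise ValueError(f"unknown input_format {cfg.input_format!r}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_protocol(cfg: ProtocolConfig,
                 ds: TelemetryDataset | None = None,
                 net: nx.Graph | None = None) -> dict:
    """Execute the protocol and write a report bundle to cfg.output_dir.

    ``ds``/``net`` may be passed directly (e.g. a fresh simulation);
    otherwise they are loaded from ``cfg.input_path``.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if net is None and ds is not None:
        net = build_network(ds, cfg.thresholds, matching=cfg.matching,
                            window=cfg.window, min_denominator=cfg.min_denominator)
    elif net is None:
        ds, net = load_input(cfg)
    rng = np.random.default_rng(cfg.seed)
    gmetrics = set(cfg.global_metrics)
    nmetrics = set(cfg.node_metrics)
    manifest: dict = {
        "package": "telesna",
        "version": __version__,
        "config": cfg.to_dict(),
        "network": {"order": net.number_of_nodes(), "size": net.number_of_edges()},
        "steps": {},
    }
    write_graphml(net, out / "network.graphml")
    write_edgelist_csv(net, out / "edges.csv", out / "nodes.csv")
    if ds is not None:
        _write_csv(summarize_dataset(ds), out / "dataset_summary.csv")
    gm = global_metrics(net, gmetrics, weighted_paths=cfg.weighted_paths)
    _write_csv(pd.DataFrame([{"metric": k, "value": v} for k, v in sorted(gm.items())]),
               out / "global_metrics.csv")
    _write_csv(node_metrics(net, nmetrics, weighted_paths=cfg.weighted_paths).reset_index(),
               out / "node_metrics.csv")

    def stage(name):
        t0 = time.perf_counter()
        logger.info("step %s: started", name)
        return t0

    def done(name, t0, **extra):
        manifest["steps"][name] = {"status": "completed",
                                   "seconds": round(time.perf_counter() - t0, 3), **extra}
        logger.info("step %s: completed in %.1fs", name, time.perf_counter() - t0)

    # Step 1 — datastream permutation null (telemetry input only)
    if ds is not None:
        t0 = stage("step1_permutation")
        dists = null_distribution(
            ds, cfg.thresholds, gmetrics, n_perm=cfg.n_perm, rng=rng,
            matching=cfg.matching, window=cfg.window, min_denominator=cfg.min_denominator,
        )
        _write_csv(null_summary(dists), out / "step1_null_summary.csv")
        _write_csv(null_values_table(dists), out / "step1_null_values.csv")
        if cfg.make_plots:
            from .plotting import plot_null_distribution
            for m, d in sorted(dists.items()):
                plot_null_distribution(d, out / f"step1_null_{m}.png")
        done("step1_permutation", t0, n_perm=cfg.n_perm)
    else:
        manifest["steps"]["step1_permutation"] = {
            "status": "skipped",
            "reason": "prebuilt-network input: associations already known",
        }

    # Step 2 — subsampling from the observed network
    t0 = stage("step2_subsampling")
    sub_tab = subsample_distribution(net, cfg.levels, cfg.n_rep, gmetrics, rng)
    _write_csv(sub_tab, out / "step2_subsample_distribution.csv")
    if cfg.make_plots:
        from .plotting import plot_subsample_boxes
        plot_subsample_boxes(sub_tab, out / "step2_subsample_boxes.png")
    done("step2_subsampling", t0, n_rep=cfg.n_rep)

    # Step 3 — bootstrap CIs for global metrics, width vs size, calibration
    t0 = stage("step3_bootstrap_global")
    ci = bootstrap_global_ci(net, cfg.B, gmetrics, cfg.conf, rng,
                             dup_edge_rule=cfg.dup_edge_rule)
    _write_csv(ci, out / "step3_global_ci.csv")
    n = net.number_of_nodes()
    sizes = cfg.ci_sizes or sorted({max(4, int(round(f * n))) for f in (0.2, 0.4, 0.6, 0.8, 1.0)})
    width_tab = ci_width_vs_samplesize(net, sizes, cfg.B, gmetrics, cfg.conf,
                                       cfg.n_outer, rng, dup_edge_rule=cfg.dup_edge_rule)
    _write_csv(width_tab, out / "step3_ci_width_vs_size.csv")
    overlap = (
        split_half_calibration(net, cfg.B, "density", cfg.split_trials, cfg.conf, rng,
                               dup_edge_rule=cfg.dup_edge_rule)
        if n >= 4 else np.nan
    )
    _write_csv(pd.DataFrame([{"metric": "density", "n_trials": cfg.split_trials,
                              "overlap_proportion": overlap}]),
               out / "step3_split_half_calibration.csv")
    if cfg.make_plots:
        from .plotting import plot_ci_width
        plot_ci_width(width_tab, out / "step3_ci_width.png")
    done("step3_bootstrap_global", t0, B=cfg.B)

    # Step 4 — partial-vs-full node-metric correlation and regression
    t0 = stage("step4_node_stability")
    usable_levels = [lv for lv in cfg.corr_levels if round(lv * n) >= 3]
    if len(usable_levels) < len(cfg.corr_levels):
        logger.warning("dropping correlation levels below 3 nodes (N=%d): %s",
                       n, sorted(set(cfg.corr_levels) - set(usable_levels)))
    corr_summary, corr_repeats = node_metric_correlation(
        net, usable_levels, nmetrics, cfg.corr_n_rep, cfg.corr_method, rng,
        return_repeats=True,
    )
    _write_csv(corr_summary, out / "step4_correlation_summary.csv")
    _write_csv(corr_repeats, out / "step4_correlation_repeats.csv")
    reg_frames = [
        node_metric_regression(net, lv, m, cfg.corr_n_rep, rng)
        for lv in usable_levels for m in sorted(nmetrics)
    ]
    _write_csv(pd.concat(reg_frames, ignore_index=True), out / "step4_regression.csv")
    if cfg.make_plots:
        from .plotting import plot_correlation_ribbon
        plot_correlation_ribbon(corr_summary, out / "step4_correlation.png")
    done("step4_node_stability", t0, levels=usable_levels)

    # Step 5 — bootstrap CIs for node-level metrics
    t0 = stage("step5_bootstrap_node")
    node_ci = bootstrap_node_ci(net, cfg.B, nmetrics, cfg.conf, rng,
                                dup_edge_rule=cfg.dup_edge_rule)
    _write_csv(node_ci, out / "step5_node_ci.csv")
    if cfg.make_plots:
        from .plotting import plot_node_ci_caterpillar
        for m in sorted(nmetrics):
            plot_node_ci_caterpillar(node_ci, m, out / f"step5_node_ci_{m}.png")
    done("step5_bootstrap_node", t0, B=cfg.B)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
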