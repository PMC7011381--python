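"""End-to-end recovery analysis over the factorial design.

One call runs, per habitat: alpha diversity, generalized-UniFrac distances,
per-timepoint pairwise divergence tests (PERMANOVA / MRPP / dispersion,
BH-adjusted per test family), per-stratum Sloan-model fits, sample
correlation networks with centrality summaries, and a distance-to-control
recovery trajectory.  Everything is deterministic given the config seed;
all outputs are tab-separated tables plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from . import __version__
from .core_io import (
    TIMEPOINTS,
    CountTable,
    read_count_table,
    read_metadata,
    read_newick,
    write_distance_matrix,
)
from .community_tests import pairwise_permutation_tests, permanova
from .diversity import alpha_diversity, gunifrac, rarefy
from .networks import build_network, centrality_shift_summary, spearman_matrix
from .neutral_model import fit_ncm_by_stratum, neutral_fraction_summary

__all__ = ["AnalysisConfig", "RecoveryReport", "run_full_analysis", "recovery_trajectory"]


@dataclass
class AnalysisConfig:
    """Paths, test parameters and the master seed for one full run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    out_dir: str | None = None
    gunifrac_alpha: float = 0.5
    n_perm: int = 199
    sig_alpha: float = 0.05
    rho_min: dict = field(default_factory=lambda: {"water": 0.5, "skin": 0.3, "gut": 0.3})
    fdr_alpha: float = 0.05
    ncm_d: int = 1
    ncm_ci: float = 0.95
    rarefy_depth: int | None = None
    control: str = "Ctrl"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.sig_alpha < 1.0):
            raise ValueError("sig_alpha must be in (0, 1)")


@dataclass
class RecoveryReport:
    alpha_table: pd.DataFrame
    beta_table: pd.DataFrame
    ncm_summary: pd.DataFrame
    network_summary: pd.DataFrame
    distances: dict[str, DistanceMatrix] = field(repr=False)
    metadata: pd.DataFrame = field(repr=False)
    config: AnalysisConfig = None
    warnings: list[str] = field(default_factory=list)


def _stage_seed(master: int, *tags: str) -> int:
    h = zlib.crc32("/".join(tags).encode())
    return int((master ^ h) % (2**31 - 1))


def _tp_order(tps) -> list[str]:
    return [t for t in TIMEPOINTS if t in set(tps)]


def run_full_analysis(
    cfg: AnalysisConfig,
    counts: CountTable | None = None,
    metadata: pd.DataFrame | None = None,
    tree=None,
) -> RecoveryReport:
    """Run every stage; inputs may be passed in memory or read from the
    config paths.  Report tables cover every (habitat, timepoint, pair)
    cell of the design; writes TSVs plus a manifest when out_dir is set."""
    if counts is None:
        counts = read_count_table(cfg.counts_path)
    if metadata is None:
        metadata = read_metadata(cfg.metadata_path)
    if tree is None and cfg.tree_path:
        tree = read_newick(cfg.tree_path)
    if tree is None:
        raise ValueError("a phylogenetic tree is required (tree or tree_path)")
    if cfg.rarefy_depth is not None:
        counts = rarefy(counts, cfg.rarefy_depth, seed=_stage_seed(cfg.seed, "rarefy"))

    meta = metadata.set_index("sample_id")
    meta = meta.loc[[s for s in counts.sample_ids if s in meta.index]]
    collected_warnings: list[str] = []

    alpha_frames, beta_rows, net_frames = [], [], []
    distances: dict[str, DistanceMatrix] = {}
    ncm_fits_all: dict[tuple, object] = {}

    for habitat in sorted(meta["habitat"].unique()):
        hab_ids = meta.index[meta["habitat"] == habitat].tolist()
        hab_counts = counts.select_samples(hab_ids).drop_empty_samples()
        hab_meta = meta.loc[hab_counts.sample_ids]

        adf = alpha_diversity(hab_counts)
        alpha_frames.append(adf.join(hab_meta))

        dm = gunifrac(hab_counts, tree, alpha=cfg.gunifrac_alpha, prune_missing=True)
        distances[habitat] = dm

        for tp in _tp_order(hab_meta["timepoint"].unique()):
            cell = hab_meta.index[hab_meta["timepoint"] == tp].tolist()
            labels = hab_meta.loc[cell, "treatment"]
            level_counts = labels.value_counts()
            usable = level_counts[level_counts >= 2]
            if len(usable) < 2:
                collected_warnings.append(
                    f"{habitat}/{tp}: fewer than two treatment groups with >= 2 samples"
                )
                continue
            keep = labels[labels.isin(usable.index)].index.tolist()
            sub_dm = dm.filter(keep)
            sub_labels = labels.loc[keep]
            seed_cell = _stage_seed(cfg.seed, "beta", habitat, tp)
            overall = permanova(sub_dm, sub_labels, n_perm=cfg.n_perm, seed=seed_cell)
            beta_rows.append(
                {
                    "habitat": habitat, "timepoint": tp, "group_a": "All", "group_b": "All",
                    "test": "permanova", "statistic": overall.statistic,
                    "p": overall.p_value, "p_adj": np.nan, "effect_size": np.nan,
                }
            )
            if len(usable) >= 2:
                pw = pairwise_permutation_tests(
                    sub_dm, sub_labels, n_perm=cfg.n_perm, seed=seed_cell
                )
                pw.insert(0, "timepoint", tp)
                pw.insert(0, "habitat", habitat)
                beta_rows.extend(pw.to_dict("records"))

        strata_fits = fit_ncm_by_stratum(
            hab_counts,
            hab_meta.reset_index(),
            ["treatment", "timepoint"],
            d=cfg.ncm_d,
            ci_level=cfg.ncm_ci,
        )
        for (trt, tp), fit in strata_fits.items():
            ncm_fits_all[(habitat, trt, tp)] = fit

        nets = {}
        for (trt, tp), grp in hab_meta.groupby(["treatment", "timepoint"], observed=True):
            cell_ids = grp.index.tolist()
            if len(cell_ids) < 3:
                nets[(trt, tp)] = _empty_net(cell_ids)
                continue
            cell_counts = hab_counts.select_samples(cell_ids)
            rho, p = spearman_matrix(cell_counts)
            node_attrs = alpha_diversity(cell_counts)[["richness"]].join(
                hab_meta.loc[cell_ids, ["treatment", "habitat", "timepoint"]]
            )
            nets[(trt, tp)] = build_network(
                rho, p,
                rho_min=cfg.rho_min.get(habitat, 0.5),
                fdr_alpha=cfg.fdr_alpha,
                node_attrs=node_attrs,
            )
        summ = centrality_shift_summary(nets, control=cfg.control)
        summ.insert(0, "habitat", habitat)
        net_frames.append(summ)

    alpha_table = pd.concat(alpha_frames).rename_axis("sample_id").reset_index()
    beta_table = pd.DataFrame(beta_rows)
    ncm_summary = neutral_fraction_summary(
        ncm_fits_all, strata_names=["habitat", "treatment", "timepoint"]
    )
    network_summary = pd.concat(net_frames, ignore_index=True)

    report = RecoveryReport(
        alpha_table=alpha_table,
        beta_table=beta_table,
        ncm_summary=ncm_summary,
        network_summary=network_summary,
        distances=distances,
        metadata=meta.reset_index(),
        config=cfg,
        warnings=collected_warnings,
    )
    if cfg.out_dir:
        _write_report(report, Path(cfg.out_dir))
    return report


def _empty_net(ids):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.graph["undefined_pairs"] = []
    return g


def _write_report(report: RecoveryReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.alpha_table.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False, float_format=fmt)
    report.beta_table.to_csv(out / "beta_divergence.tsv", sep="\t", index=False, float_format=fmt)
    report.ncm_summary.to_csv(out / "ncm_summary.tsv", sep="\t", index=False, float_format=fmt)
    report.network_summary.to_csv(
        out / "network_centrality.tsv", sep="\t", index=False, float_format=fmt
    )
    for habitat, dm in report.distances.items():
        write_distance_matrix(dm, out / f"gunifrac_{habitat}.tsv")
    for habitat in report.distances:
        try:
            traj = recovery_trajectory(report, habitat)
            traj.to_csv(out / f"trajectory_{habitat}.tsv", sep="\t", index=False, float_format=fmt)
        except ValueError:
            pass
    manifest = {
        "package": "recoverymics",
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(report.config).items()
        },
        "n_samples": int(len(report.metadata)),
        "habitats": sorted(report.distances),
        "warnings": report.warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def recovery_trajectory(
    report: RecoveryReport, habitat: str, alpha: float | None = None
) -> pd.DataFrame:
    """Mean between-group distance control ↔ treatment per timepoint, with a
    within-control baseline and a terminal ``recovered`` flag.

    A treatment is called recovered when its terminal-timepoint pairwise
    PERMANOVA contrast against control is non-significant (p_adj > alpha) —
    one defensible operationalization of trajectory convergence.
    """
    if habitat not in report.distances:
        raise ValueError(f"habitat {habitat!r} not in report")
    cfg = report.config
    control = cfg.control if cfg else "Ctrl"
    alpha = alpha if alpha is not None else (cfg.sig_alpha if cfg else 0.05)
    dm = report.distances[habitat]
    meta = report.metadata.set_index("sample_id")
    meta = meta.loc[[i for i in dm.ids if i in meta.index]]
    tps = _tp_order(meta["timepoint"].unique())
    treatments = [t for t in sorted(meta["treatment"].unique()) if t != control]
    if not treatments:
        raise ValueError("no non-control treatment in this habitat")
    data = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)

    beta = report.beta_table
    rows = []
    for trt in treatments:
        terminal = tps[-1]
        term = beta[
            (beta["habitat"] == habitat)
            & (beta["timepoint"] == terminal)
            & (beta["test"] == "permanova")
            & (
                ((beta["group_a"] == control) & (beta["group_b"] == trt))
                | ((beta["group_a"] == trt) & (beta["group_b"] == control))
            )
        ]
        recovered = bool(len(term)) and bool((term["p_adj"] > alpha).all())
        for tp in tps:
            ctrl_ids = meta.index[(meta["treatment"] == control) & (meta["timepoint"] == tp)]
            trt_ids = meta.index[(meta["treatment"] == trt) & (meta["timepoint"] == tp)]
            if len(ctrl_ids) == 0 or len(trt_ids) == 0:
                rows.append(
                    {
                        "habitat": habitat, "treatment": trt, "timepoint": tp,
                        "mean_distance_to_control": np.nan,
                        "within_control_distance": np.nan,
                        "recovered_at_terminal": recovered,
                    }
                )
                continue
            between = data.loc[ctrl_ids, trt_ids].to_numpy().mean()
            cc = data.loc[ctrl_ids, ctrl_ids].to_numpy()
            n_c = len(ctrl_ids)
            within = cc.sum() / (n_c * (n_c - 1)) if n_c > 1 else np.nan
            rows.append(
                {
                    "habitat": habitat, "treatment": trt, "timepoint": tp,
                    "mean_distance_to_control": float(between),
                    "within_control_distance": float(within),
                    "recovered_at_terminal": recovered,
                }
            )
    return pd.DataFrame(rows)
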