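"""End-to-end orchestration: simulate -> LEL -> bin -> EC -> DE -> network
-> biomarker, from one config, with deterministic seeding and
machine-readable outputs.

Every stage writes its intermediate artifact under the output directory;
``summary.json`` records the seed, the stage parameters, and per-stage
headline numbers (bin sizes, DEG counts, edge count, cluster labels,
marker concordance).  The same config and seed reproduce every byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import _io
from .biomarker import cluster_marker_concordance, cur_correlation, deg_overlap, marker_status
from .doseresponse import ec_p, fit_ll4
from .expression import (
    condition_means,
    de_table,
    filter_degs,
    flag_outlier_replicates,
    size_factors,
    top_cv_genes,
)
from .network import clr_z, condition_clusters, mi_matrix, network_edges
from .phenotypes import assign_bins, encode_lel_matrix, lel_profiles
from .simulate import (
    default_burden_config,
    default_expression_config,
    default_screen_config,
    generate_body_burden,
    generate_expression_study,
    generate_phenotype_screen,
)


@dataclass
class RunConfig:
    """Stage parameters (study defaults) plus seeding and output location."""

    seed: int = 0
    outdir: str = "pahtox_run"
    alpha: float = 0.05
    fc_min: float = 1.5
    top_n: int = 500
    z_threshold: float = 1.0
    n_bins: int = 8
    mi_bins: int | None = None
    z_mode: str = "clr"
    ec_percent: float = 80.0
    log_kow_max: float = 5.5
    n_genes: int = 2000
    n_chemicals: int = 64

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on freshly simulated inputs; return the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "pahtox_version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
    }

    # --- simulate ---------------------------------------------------------
    screen_cfg = default_screen_config(n_chemicals=config.n_chemicals, seed=config.seed)
    incidence, screen_truth, cyp1a_flags = generate_phenotype_screen(screen_cfg)
    expr_cfg = default_expression_config(n_genes=config.n_genes, seed=config.seed)
    counts, meta, truth = generate_expression_study(expr_cfg)
    burden = generate_body_burden(default_burden_config(seed=config.seed))
    _io.write_table(incidence, out / "incidence.tsv")
    _io.write_matrix(counts, out / "counts.tsv", index_label="gene")
    _io.write_table(meta, out / "metadata.tsv")
    _io.write_table(burden, out / "body_burden.tsv")
    _io.write_json(truth, out / "truth.json")

    # --- LEL + binning ----------------------------------------------------
    profiles = lel_profiles(incidence, cyp1a_flags=cyp1a_flags, alpha=config.alpha)
    lel_matrix = encode_lel_matrix(profiles)
    bins, bin_linkage = assign_bins(lel_matrix, k=config.n_bins)
    _io.write_matrix(lel_matrix, out / "lel_matrix.tsv", index_label="chemical")
    _io.write_table(bins.reset_index().set_axis(["chemical", "bin"], axis=1), out / "bins.tsv")
    if bin_linkage is not None:
        (out / "bins_dendrogram.nwk").write_text(
            _io.linkage_to_newick(bin_linkage, list(lel_matrix.index)) + "\n"
        )
    summary["bins"] = {
        "n_chemicals": int(len(bins)),
        "bin_sizes": {int(b): int(n) for b, n in bins.value_counts().sort_index().items()},
    }

    # --- EC estimation ----------------------------------------------------
    # fit the most sensitive endpoint (smallest LEL) per chemical
    ec_rows = []
    for p in profiles:
        active = {ep: lel for ep, lel in p.lel.items() if lel is not None}
        if not active:
            continue
        endpoint = min(active, key=lambda ep: (active[ep], ep))
        sub = incidence.loc[
            (incidence["chemical"] == p.chemical)
            & (incidence["endpoint"] == endpoint)
            & (incidence["conc_uM"] > 0)
        ]
        fit = fit_ll4(
            sub["conc_uM"], sub["n_affected"] / sub["n_total"], weights=sub["n_total"]
        )
        if not fit.converged:
            continue
        est = ec_p(
            fit.params,
            config.ec_percent,
            tested_range=(sub["conc_uM"].min(), sub["conc_uM"].max()),
        )
        ec_rows.append(
            {
                "chemical": p.chemical,
                "endpoint": endpoint,
                "b": fit.params.b,
                "c": fit.params.c,
                "d": fit.params.d,
                "e": fit.params.e,
                "rss": fit.rss,
                f"ec{config.ec_percent:g}": est.dose,
                "extrapolated": est.extrapolated,
            }
        )
    ec_df = pd.DataFrame(ec_rows)
    _io.write_table(ec_df, out / "ec_estimates.tsv")
    summary["ec"] = {"n_fitted": int(len(ec_df))}

    # --- DE ---------------------------------------------------------------
    factors = size_factors(counts)
    keep = flag_outlier_replicates(counts, meta, factors=factors)
    _io.write_json(
        {"retained": sorted(keep.index[keep]), "dropped": sorted(keep.index[~keep])},
        out / "retained_samples.json",
    )
    treatments = sorted(meta.loc[~meta["is_control"].astype(bool), "treatment"].unique())
    deg_sets = {}
    deg_counts = {}
    marker_statuses = []
    for treatment in treatments:
        de = de_table(counts, meta, treatment, factors=factors, keep=keep)
        _io.write_matrix(de, out / f"de_{_slug(treatment)}.tsv", index_label="gene")
        degs = filter_degs(de, treatment=treatment, fc_min=config.fc_min, alpha=config.alpha)
        deg_sets[treatment] = degs
        deg_counts[treatment] = len(degs.genes)
        marker_statuses.append(
            marker_status(de, condition=treatment, marker=truth["marker_gene"], alpha=config.alpha)
        )
    _io.write_table(
        pd.DataFrame(
            [
                {
                    "treatment": t,
                    "n_degs": deg_counts[t],
                    "n_elevated": len(deg_sets[t].elevated),
                    "n_reduced": len(deg_sets[t].reduced),
                }
                for t in treatments
            ]
        ),
        out / "deg_counts.tsv",
    )
    summary["de"] = {
        "n_dropped_replicates": int((~keep).sum()),
        "deg_counts": {t: int(deg_counts[t]) for t in treatments},
    }

    # --- network ----------------------------------------------------------
    cm = condition_means(counts, meta, factors=factors, keep=keep)
    top_genes = top_cv_genes(cm, n=config.top_n)
    (out / "top_cv_genes.txt").write_text("\n".join(top_genes) + "\n")
    cm_top = cm[top_genes]
    mim = mi_matrix(cm_top, bins=config.mi_bins)
    zres = clr_z(mim, mode=config.z_mode)
    edges = network_edges(zres, threshold=config.z_threshold)
    controls = truth["controls"]
    labels, cond_linkage = condition_clusters(cm_top, controls=controls)
    _io.write_matrix(mim, out / "mi_matrix.tsv", index_label="condition")
    _io.write_matrix(zres.values, out / "z_matrix.tsv", index_label="condition")
    _io.write_table(edges, out / "edges.tsv")
    _io.write_graphml(edges, out / "network.graphml", nodes=list(cm.index))
    _io.write_table(
        labels.reset_index().set_axis(["condition", "cluster"], axis=1),
        out / "condition_clusters.tsv",
    )
    (out / "conditions_dendrogram.nwk").write_text(
        _io.linkage_to_newick(cond_linkage, list(cm_top.index)) + "\n"
    )
    summary["network"] = {
        "n_nodes": int(cm.shape[0]),
        "n_edges": int(len(edges)),
        "z_mode": zres.mode,
        "cluster_labels": {str(c): str(l) for c, l in labels.items()},
        "cluster_sizes": {str(k): int(v) for k, v in labels.value_counts().sort_index().items()},
    }

    # --- biomarker --------------------------------------------------------
    treatment_labels = labels.drop(labels=controls)
    conc = cluster_marker_concordance(treatment_labels, marker_statuses)
    _io.write_table(
        pd.DataFrame(
            [
                {
                    "condition": s.condition,
                    "marker_log2fc": s.marker_log2fc,
                    "marker_padj": s.marker_padj,
                    "elevated": s.elevated,
                }
                for s in marker_statuses
            ]
        ),
        out / "marker_status.tsv",
    )
    _io.write_json(
        {
            "concordance": conc["concordance"],
            "table": [[int(x) for x in row] for row in conc["table"]],
            "fisher_p": conc["fisher_p"],
        },
        out / "concordance.json",
    )
    b_sets = {
        t: deg_sets[t].genes
        for t, lab in treatment_labels.items()
        if lab == "B" and deg_sets[t].genes
    }
    overlap_summary = {}
    if len(b_sets) >= 2:
        shared, unique, pairwise = deg_overlap(b_sets)
        _io.write_json(
            {
                "shared": sorted(shared),
                "unique": {t: sorted(u) for t, u in unique.items()},
                "pairwise": pairwise.to_dict(),
            },
            out / "deg_overlap.json",
        )
        overlap_summary = {"n_shared": len(shared), "n_sets": len(b_sets)}
    cur_res, cur_summary = cur_correlation(
        burden,
        {c: deg_counts.get(c, 0) for c in burden["chemical"].unique()},
        log_kow_max=config.log_kow_max,
    )
    _io.write_table(cur_summary.reset_index(), out / "cur_summary.tsv")
    summary["biomarker"] = {
        "n_elevated": int(sum(s.elevated for s in marker_statuses)),
        "concordance": conc["concordance"],
        "fisher_p": conc["fisher_p"],
        "deg_overlap": overlap_summary,
        "cur_r2": cur_res.r2,
        "cur_p": cur_res.p,
        "cur_n": cur_res.n,
    }

    _io.write_json(summary, out / "summary.json")
    return summary


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in name)
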