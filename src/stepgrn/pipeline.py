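"""End-to-end orchestration: simulate -> degs -> chromatin -> associate ->
network, with a run manifest for provenance.

Each stage is a function over files so it can run standalone (CLI
subcommands) or inside :func:`run_all`; identical config + seed yields
byte-identical output bundles (the manifest records parameters and
checksums, never wall-clock state).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    annotate_crms,
    association_matrix,
    cluster_associations,
    integrate_states_pathways,
    neglog10_pivot,
    select_tfs,
)
from .chromatin import (
    call_presence,
    cluster_census,
    compute_peak_evidence,
    median_profile,
    quantile_normalize,
    state_trajectories,
    write_presence,
    write_trajectories,
    zscore_scale,
)
from .config import MARKS, ConfigurationError, PipelineConfig, SimulationConfig
from .expression import call_degs, pathway_summary, read_deg_table, write_deg_table
from .chromatin import read_presence
from .io import (
    read_crm_catalog,
    read_expression,
    read_gmt,
    read_peaks,
)
from .network import (
    assemble_grn,
    export_grn,
    filter_oncogene_targets,
    node_metrics,
    reduce_network,
)
from .synthetic import simulate_all

log = logging.getLogger("stepgrn.pipeline")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise ConfigurationError(f"missing {what}: {path}")
    return path


# ---------------------------------------------------------------------------
# stages


def run_degs(config: PipelineConfig, indir, outdir) -> pd.DataFrame:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = read_expression(
        _require(indir / "expression.tsv", "expression matrix"),
        _require(indir / "design.tsv", "sample design"),
    )
    stages = tuple(dict.fromkeys(matrix.design["stage"]))
    table = call_degs(
        matrix,
        fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha,
        stages=stages, var_prior_df=config.var_prior_df,
        bh_correct=config.bh_correct, pattern_mapping=config.pattern_mapping,
    )
    write_deg_table(table, outdir / "degs.tsv")
    summary = pathway_summary(table)
    with open(outdir / "deg_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("degs: %s DEGs of %d genes", summary["n_degs"], len(table))
    return table


def _load_tracks(indir: Path, stages):
    from .io import read_track

    raw = {}
    for mark in MARKS:
        for stage in stages:
            path = _require(
                indir / "coverage" / f"{mark}_{stage}.bedgraph",
                f"coverage track {mark}/{stage}",
            )
            raw[(mark, stage)] = read_track(path, mark, stage)
    return raw


def run_chromatin(config: PipelineConfig, indir, outdir, stages) -> pd.DataFrame:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import read_tss_bed

    tss = read_tss_bed(_require(indir / "tss.bed", "TSS annotation"))
    raw = _load_tracks(indir, stages)

    # normalize: quantile across stages per mark, then z across everything
    z_tracks = {}
    for mark in MARKS:
        group = [raw[(mark, stage)] for stage in stages]
        for track in zscore_scale(quantile_normalize(group)):
            z_tracks[(mark, track.stage)] = track

    evidence_frames = []
    for mi, mark in enumerate(MARKS):
        for si, stage in enumerate(stages):
            peaks = read_peaks(
                _require(indir / "peaks" / f"{mark}_{stage}.narrowPeak",
                         f"peak file {mark}/{stage}")
            )
            child = np.random.SeedSequence((config.seed, mi, si))
            sub_seed = int(child.generate_state(1)[0] >> 1)
            evidence_frames.append(
                compute_peak_evidence(
                    peaks, raw[(mark, stage)], z_tracks[(mark, stage)],
                    fractions=config.subsample_fractions,
                    reps=config.subsample_reps, seed=sub_seed,
                )
            )
    evidence = pd.concat(evidence_frames, ignore_index=True)

    presence = call_presence(
        evidence, tss, stages,
        window=config.window, zmin=config.zmin,
        max_dispersion=config.max_dispersion,
    )
    write_presence(presence, outdir / "marks.tsv")
    trajectories = state_trajectories(presence, stages, config.bivalent_closure)
    write_trajectories(trajectories, outdir / "trajectories.tsv")
    census = cluster_census(trajectories)
    census.to_csv(outdir / "state_clusters.tsv", sep="\t")

    # median display profiles for the populated clusters
    profiles = []
    for cluster in census.index[census >= 5][:20]:
        genes = trajectories.index[trajectories["cluster"] == cluster]
        profile = median_profile(genes, z_tracks, tss, flank=config.profile_flank)
        profile = profile.reset_index()
        profile.insert(0, "cluster", cluster)
        profiles.append(profile)
    if profiles:
        pd.concat(profiles, ignore_index=True).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False, float_format="%.4f"
        )
    log.info("chromatin: %d transition clusters over %d genes",
             len(census), len(trajectories))
    return trajectories


def run_associate(config: PipelineConfig, indir, outdir) -> dict:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    degs = read_deg_table(_require(outdir / "degs.tsv", "DEG table"))
    regulons = read_gmt(_require(indir / "regulons.gmt", "regulon database"))
    presence = read_presence(_require(outdir / "marks.tsv", "mark matrix"))

    tfs = select_tfs(
        regulons, degs, presence,
        min_cover=config.min_cover, pol2_stage=config.pol2_stage,
    )
    matrix = association_matrix(
        regulons, tfs, degs, universe=list(degs.index),
        neglog10_cap=config.neglog10_cap,
    )
    matrix.to_csv(outdir / "associations.tsv", sep="\t", index=False, float_format="%.6g")
    if len(tfs) >= 1 and len(matrix):
        pivot = neglog10_pivot(matrix)
        row_order, col_order = cluster_associations(
            pivot, method=config.linkage_method, metric=config.linkage_metric
        )
        pivot.loc[row_order, col_order].to_csv(
            outdir / "association_matrix.tsv", sep="\t", float_format="%.4f"
        )

    from .chromatin import read_trajectories

    trajectories = read_trajectories(outdir / "trajectories.tsv")
    observed, expected, residuals, enriched = integrate_states_pathways(
        trajectories, degs, residual_enrichment=config.residual_enrichment
    )
    observed.to_csv(outdir / "integration_observed.tsv", sep="\t")
    residuals.to_csv(outdir / "integration_residuals.tsv", sep="\t", float_format="%.4f")

    crm_path = indir / "crm_catalog.tsv"
    crms = annotate_crms(degs, read_crm_catalog(crm_path) if crm_path.exists() else None)
    crms.to_csv(outdir / "crms.tsv", sep="\t")
    log.info("associate: %d candidate TFs, %d DEG CRMs", len(tfs), len(crms))
    return {"tfs": tfs, "residuals": residuals}


def run_network(config: PipelineConfig, indir, outdir, oncogene: str = "") -> dict:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import read_sif, read_tss_bed

    degs = read_deg_table(_require(outdir / "degs.tsv", "DEG table"))
    interactions = read_sif(_require(indir / "interactions.sif", "interaction edges"))
    regulons = read_gmt(_require(indir / "regulons.gmt", "regulon database"))
    presence = read_presence(_require(outdir / "marks.tsv", "mark matrix"))
    tss = read_tss_bed(_require(indir / "tss.bed", "TSS annotation"))
    tfs = select_tfs(
        regulons, degs, presence,
        min_cover=config.min_cover, pol2_stage=config.pol2_stage,
    )

    onco_path = indir / "oncogene_peaks.narrowPeak"
    onco_targets: list[str] = []
    if onco_path.exists():
        onco_targets = filter_oncogene_targets(
            read_peaks(onco_path), tss,
            promoter_window=config.promoter_window, minlogp=config.minlogp,
        )

    crm_path = indir / "crm_catalog.tsv"
    catalog = read_crm_catalog(crm_path) if crm_path.exists() else None
    graph = assemble_grn(
        degs, interactions, regulons, tfs,
        oncogene=oncogene or None, oncogene_targets=onco_targets,
        crm_catalog=catalog,
    )
    metrics = node_metrics(graph, epsilon=config.epsilon)
    metrics.to_csv(outdir / "node_metrics.tsv", sep="\t", float_format="%.6g")
    export_grn(graph, outdir / "grn.sif", outdir / "grn_nodes.tsv",
               outdir / "grn_edges.tsv")
    reduced = reduce_network(graph, metrics, config.k_hubs, config.k_bottlenecks)
    export_grn(reduced, outdir / "grn_reduced.sif", outdir / "grn_reduced_nodes.tsv",
               outdir / "grn_reduced_edges.tsv")
    log.info(
        "network: %d nodes / %d edges, reduced to %d nodes / %d edges",
        graph.number_of_nodes(), graph.number_of_edges(),
        reduced.number_of_nodes(), reduced.number_of_edges(),
    )
    return {"graph": graph, "reduced": reduced, "metrics": metrics,
            "oncogene_targets": onco_targets}


# ---------------------------------------------------------------------------
# run_all + manifest


def run_all(
    config: PipelineConfig,
    indir,
    outdir,
    simulate: SimulationConfig | None = None,
    oncogene: str = "",
) -> dict:
    """Execute every stage; optionally generate the inputs first.

    When ``simulate`` is given the input bundle is written to ``indir`` and
    the planted oncogene is used for ChIP-edge anchoring unless ``oncogene``
    overrides it.  Returns a summary dict; writes ``manifest.json``.
    """
    indir, outdir = Path(indir), Path(outdir)
    gold = None
    if simulate is not None:
        gold = simulate_all(simulate, indir)
        oncogene = oncogene or gold.oncogene
    stages_path = _require(indir / "design.tsv", "sample design")
    design = pd.read_csv(stages_path, sep="\t", index_col="sample")
    stages = tuple(dict.fromkeys(design["stage"]))

    degs = run_degs(config, indir, outdir)
    run_chromatin(config, indir, outdir, stages)
    run_associate(config, indir, outdir)
    net = run_network(config, indir, outdir, oncogene=oncogene)

    manifest = {
        "package": "stepgrn",
        "version": __version__,
        "seed": config.seed,
        "oncogene": oncogene,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "pattern_mapping"
        },
        "pattern_mapping": {
            f"{a},{b}": lab for (a, b), lab in sorted(config.pattern_mapping.items())
        },
        "simulation": (
            None if simulate is None else
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(simulate).items()}
        ),
        "inputs": {
            str(p.relative_to(indir)): _sha256(p)
            for p in sorted(indir.rglob("*")) if p.is_file()
        },
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    summary = pathway_summary(degs)
    summary["grn_nodes"] = net["graph"].number_of_nodes()
    summary["grn_edges"] = net["graph"].number_of_edges()
    summary["reduced_nodes"] = net["reduced"].number_of_nodes()
    summary["reduced_edges"] = net["reduced"].number_of_edges()
    return {"summary": summary, "gold": gold, "network": net}
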