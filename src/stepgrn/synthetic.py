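"""Synthetic-data generator with planted ground truth for every stage.

Emulates the full input bundle of the stepwise-transformation analysis on a
toy genome (one linear chromosome, TSSs 10 kb apart so promoter windows
never interact):

* an expression matrix with seven planted co-expression pathways (constant
  |log2 ratio| = effect_size at each planted change, replicate noise
  ~ Normal(0, noise_sd));
* per-mark, per-stage binned coverage tracks and peak calls whose
  TSS-proximal peaks realize each gene's planted chromatin state (the
  state's defining marks are emitted jointly with probability
  ``state_emission``; background peaks sit away from TSSs and in the bulk of
  the intensity distribution, planted peaks in its upper tail, so the
  z > 1.65 gate separates them by construction);
* a regulon database whose driver TFs are enriched in one pathway each;
* a scale-free interaction network of preferential-attachment communities
  aligned with pathways, engineered high-MNC hubs (spoke-and-ring
  neighborhoods), high-DMNC clique nodes, and connector nodes that are the
  sole links between adjacent communities;
* an oncogene ChIP peak file whose -log10(p) >= 300 peaks mark exactly the
  designated target promoters.

All randomness flows from a single seed through named child streams, so a
seed fixes every output byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import STATE_DEFINING_MARKS
from .config import (
    MARKS,
    NO_PATHWAY,
    PATHWAY_LABELS,
    ConfigurationError,
    SimulationConfig,
)
from .io import (
    ExpressionMatrix,
    GoldStandard,
    write_crm_catalog,
    write_expression,
    write_gmt,
    write_peaks,
    write_sif,
    write_track,
    write_tss_bed,
)

log = logging.getLogger("stepgrn.simulate")

#: Canonical per-step call pattern realized for each planted pathway label.
PATTERN_BY_LABEL: dict[str, tuple[str, str]] = {
    "i": ("up", "ns"),
    "ii": ("up", "down"),
    "iii": ("down", "ns"),
    "iv": ("up", "up"),
    "v": ("down", "down"),
    "vi": ("ns", "up"),
    "vii": ("ns", "down"),
}
#: The merged discordant-reversal pattern also mapped to label ii.
ALT_PATTERN_II: tuple[str, str] = ("down", "up")

#: Planted chromatin-state trajectory for each pathway (stage1>stage2>stage3).
TRAJECTORY_BY_LABEL: dict[str, tuple[str, str, str]] = {
    "i": ("bivalent", "active", "active"),
    "ii": ("bivalent", "active", "repressed"),
    "iii": ("active", "empty", "empty"),
    "iv": ("empty", "transcription_prone", "active"),
    "v": ("active", "weakly_active", "empty"),
    "vi": ("repressed", "repressed", "active"),
    "vii": ("active", "active", "repressed"),
}

#: Constant trajectories (with sampling weights) for non-DEG genes.
BACKGROUND_STATES: tuple[tuple[str, float], ...] = (
    ("active", 0.30),
    ("empty", 0.40),
    ("repressed", 0.10),
    ("transcription_prone", 0.10),
    ("ambiguous", 0.10),
)

CHROM = "chrS"
BACKGROUND_RATE = 3.0  # mean Poisson background counts per 100-bp bin
PEAK_COUNT_SCALE = 25.0  # counts per unit of planted peak intensity
BG_PEAK_COUNT_SCALE = 8.0  # counts per unit of background peak intensity
GAMMA_SHAPE, GAMMA_SCALE = 2.0, 2.0  # intensity distribution
NARROW_KERNEL = np.array([0.4, 0.8, 1.0, 0.8, 0.4])
BROAD_KERNEL = np.array([0.5, 0.7, 0.85, 0.95, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.95, 0.85, 0.7, 0.5])


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("expression", "roles", "chromatin", "network", "regulons", "oncogene")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# expression + gold labels


def simulate_expression(config: SimulationConfig, rng=None, roles_rng=None):
    """Expression matrix plus the planted gold standard skeleton.

    Genes receive pathway labels per ``pathway_proportions``; each planted
    change shifts the stage mean by +/-effect_size on the log2 scale, and
    replicates add Normal(0, noise_sd) log2 noise.  Driver TFs (one per
    pathway) and decoy TFs are designated among non-DEG genes, and every
    gene gets a planted chromatin-state trajectory consistent with its
    pathway.
    """
    config.validate()
    if rng is None:
        streams = _streams(config.seed)
        rng, roles_rng = streams["expression"], streams["roles"]
    genes = gene_ids(config.n_genes)

    # pathway assignment
    labels = np.array([NO_PATHWAY] * config.n_genes, dtype=object)
    order = rng.permutation(config.n_genes)
    cursor = 0
    for label in PATHWAY_LABELS:
        frac = float(config.pathway_proportions.get(label, 0.0))
        count = int(round(frac * config.n_genes))
        labels[order[cursor : cursor + count]] = label
        cursor += count

    # realized per-step call pattern
    patterns: list[tuple[str, str]] = []
    for label in labels:
        if label == NO_PATHWAY:
            patterns.append(("ns", "ns"))
        elif label == "ii" and rng.random() < 0.2:
            patterns.append(ALT_PATTERN_II)
        else:
            patterns.append(PATTERN_BY_LABEL[label])

    # expression values
    direction = {"up": 1.0, "down": -1.0, "ns": 0.0}
    base_log2 = rng.normal(7.0, 1.5, config.n_genes)
    stage_means = {config.stages[0]: base_log2}
    for k, stage in enumerate(config.stages[1:]):
        shift = np.array([direction[p[k]] for p in patterns]) * config.effect_size
        stage_means[stage] = base_log2 + shift
    columns = {}
    for stage in config.stages:
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_sd, config.n_genes)
            columns[f"{stage}_r{rep}"] = 2.0 ** (stage_means[stage] + noise)
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    design = pd.DataFrame(
        [
            (f"{stage}_r{rep}", stage, rep)
            for stage in config.stages
            for rep in range(1, config.n_replicates + 1)
        ],
        columns=["sample", "stage", "replicate"],
    ).set_index("sample")
    matrix = ExpressionMatrix(values=values, design=design)

    # TF roles among non-DEG genes
    non_deg = [g for g, lab in zip(genes, labels) if lab == NO_PATHWAY]
    if config.n_tfs == 0 and config.regulon_size > 0:
        raise ConfigurationError("n_tfs=0 with nonzero regulon demand")
    if config.n_tfs > len(non_deg):
        raise ConfigurationError("not enough non-DEG genes to host TFs")
    tf_genes = sorted(roles_rng.choice(non_deg, size=config.n_tfs, replace=False))
    planted_pathways = [
        lab for lab in PATHWAY_LABELS if config.pathway_proportions.get(lab, 0.0) > 0
    ]
    n_drivers = min(len(planted_pathways), config.n_tfs)
    tf_pathways = {tf_genes[k]: planted_pathways[k] for k in range(n_drivers)}
    decoys = tf_genes[n_drivers:]

    # planted chromatin-state trajectories
    bg_states = [s for s, _ in BACKGROUND_STATES]
    bg_weights = np.array([w for _, w in BACKGROUND_STATES])
    bg_weights = bg_weights / bg_weights.sum()
    trajectories = {}
    for gene, label in zip(genes, labels):
        if label == NO_PATHWAY:
            state = bg_states[int(roles_rng.choice(len(bg_states), p=bg_weights))]
            trajectories[gene] = (state, state, state)
        else:
            trajectories[gene] = TRAJECTORY_BY_LABEL[label]
    for k, tf in enumerate(tf_genes):
        if tf in tf_pathways or k % 2 == 0:
            trajectories[tf] = ("active", "active", "active")
        else:  # Pol II-free decoys exercise the promoter filter
            trajectories[tf] = ("transcription_prone",) * 3

    gold_genes = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    gold_genes["pathway"] = labels
    gold_genes["pattern_step1"] = [p[0] for p in patterns]
    gold_genes["pattern_step2"] = [p[1] for p in patterns]
    for i, stage in enumerate(config.stages):
        gold_genes[f"state_{stage}"] = [trajectories[g][i] for g in genes]
    gold_genes["is_tf"] = gold_genes.index.isin(tf_genes).astype(int)
    gold = GoldStandard(genes=gold_genes, tf_pathways=tf_pathways)
    gold.decoy_tfs = decoys  # type: ignore[attr-defined]
    return matrix, gold


# ---------------------------------------------------------------------------
# chromatin tracks + peaks


def make_tss(config: SimulationConfig, rng) -> pd.DataFrame:
    genes = gene_ids(config.n_genes)
    positions = config.tss_spacing // 2 + config.tss_spacing * np.arange(config.n_genes)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    return pd.DataFrame(
        {"chrom": CHROM, "tss": positions, "strand": strands},
        index=pd.Index(genes, name="gene_id"),
    )


def _tail_intensity(rng, size):
    """Planted peak intensity: upper 5 % tail of the gamma distribution."""
    u = rng.uniform(0.95, 0.9995, size)
    return stats.gamma.ppf(u, GAMMA_SHAPE, scale=GAMMA_SCALE)


def _bulk_intensity(rng, size):
    """Background peak intensity: bulk (5th-50th percentile) of the gamma."""
    u = rng.uniform(0.05, 0.50, size)
    return stats.gamma.ppf(u, GAMMA_SHAPE, scale=GAMMA_SCALE)


def simulate_chromatin(config: SimulationConfig, gold: GoldStandard, tss=None, rng=None):
    """Binned coverage tracks and peak calls realizing the planted states.

    For each gene and stage, the defining marks of its planted state emit a
    peak with summit within +/-400 bp of the TSS and intensity in the top
    5 % of the track's distribution — jointly, with probability
    ``state_emission`` (a failed emission drops all of the state's marks at
    that stage).  Background peaks are placed >=2 kb away from every TSS
    with bulk intensities.  Coverage is Poisson counts on 100-bp bins.

    Returns ``(tss, tracks, peaks)`` with ``tracks[(mark, stage)]`` a raw
    BinnedTrack and ``peaks[(mark, stage)]`` a narrowPeak-like DataFrame.
    """
    if rng is None:
        rng = _streams(config.seed)["chromatin"]
    if tss is None:
        tss = make_tss(config, rng)
    genes = list(gold.genes.index)
    for stage in config.stages:
        col = f"state_{stage}"
        if col not in gold.genes.columns:
            raise ConfigurationError(f"gold standard lacks {col}")
        unknown = set(gold.genes[col]) - set(STATE_DEFINING_MARKS)
        if unknown:
            raise ConfigurationError(f"unknown state labels: {sorted(unknown)}")

    n_bins = config.n_genes * (config.tss_spacing // config.bin_size)
    starts = np.arange(n_bins, dtype=np.int64) * config.bin_size
    genome_length = n_bins * config.bin_size

    # joint emission draw per gene x stage
    emitted = {
        stage: rng.random(config.n_genes) < config.state_emission
        for stage in config.stages
    }
    summit_offsets = {
        stage: rng.integers(-400, 401, config.n_genes) for stage in config.stages
    }

    from .io import BinnedTrack  # local import to avoid cycle at module load

    tracks: dict[tuple[str, str], BinnedTrack] = {}
    peaks: dict[tuple[str, str], pd.DataFrame] = {}
    tss_positions = tss["tss"].to_numpy(np.int64)

    for mark in MARKS:
        broad = mark == "H3K27me3"
        kernel = BROAD_KERNEL if broad else NARROW_KERNEL
        half_width = (len(kernel) // 2) * config.bin_size
        for stage in config.stages:
            counts = rng.poisson(BACKGROUND_RATE, n_bins).astype(np.int64)
            rows = []
            states = gold.genes[f"state_{stage}"].to_numpy()
            planted = [
                i for i in range(config.n_genes)
                if mark in STATE_DEFINING_MARKS[states[i]] and emitted[stage][i]
            ]
            amps = _tail_intensity(rng, len(planted))
            for amp, i in zip(amps, planted):
                summit = int(tss_positions[i] + summit_offsets[stage][i])
                center = summit // config.bin_size
                lo = center - len(kernel) // 2
                profile = rng.poisson(amp * PEAK_COUNT_SCALE * kernel)
                counts[lo : lo + len(kernel)] += profile
                start = summit - half_width
                end = summit + half_width + config.bin_size
                rows.append(
                    (
                        CHROM, start, end, f"{mark}_{stage}_{genes[i]}",
                        int(min(1000, amp * 50)), ".", float(amp),
                        float(10 + 5 * amp), float(8 + 4 * amp),
                        -1 if broad else summit - start,
                    )
                )
            # background peaks away from every TSS
            n_bg = max(2, config.n_genes // 10)
            bg_gene = rng.integers(0, config.n_genes, n_bg)
            side = rng.random(n_bg) < 0.5
            offset = rng.integers(2000, config.tss_spacing // 2 - 500, n_bg)
            bg_summits = tss_positions[bg_gene] + np.where(side, offset, -offset)
            bg_amps = _bulk_intensity(rng, n_bg)
            for summit, amp in zip(bg_summits, bg_amps):
                summit = int(np.clip(summit, half_width, genome_length - half_width - 1))
                center = summit // config.bin_size
                lo = center - len(kernel) // 2
                profile = rng.poisson(amp * BG_PEAK_COUNT_SCALE * kernel)
                counts[lo : lo + len(kernel)] += profile
                start = summit - half_width
                end = summit + half_width + config.bin_size
                rows.append(
                    (
                        CHROM, start, end, f"{mark}_{stage}_bg{summit}",
                        int(min(1000, amp * 50)), ".", float(amp),
                        float(10 + 5 * amp), float(8 + 4 * amp),
                        -1 if broad else summit - start,
                    )
                )
            peak_frame = pd.DataFrame(
                rows,
                columns=[
                    "chrom", "start", "end", "name", "score", "strand",
                    "signal", "neglog10_p", "neglog10_q", "summit_offset",
                ],
            ).sort_values(["start", "name"], kind="mergesort", ignore_index=True)
            midpoint = (peak_frame["start"] + peak_frame["end"]) // 2
            peak_frame["summit"] = np.where(
                peak_frame["summit_offset"] >= 0,
                peak_frame["start"] + peak_frame["summit_offset"],
                midpoint,
            )
            tracks[(mark, stage)] = BinnedTrack(
                target=mark, stage=stage, chrom=CHROM, bin_size=config.bin_size,
                starts=starts.copy(), values=counts.astype(float),
            )
            peaks[(mark, stage)] = peak_frame
    return tss, tracks, peaks


# ---------------------------------------------------------------------------
# regulons, interaction network, oncogene ChIP


def _pathway_blocks(gold: GoldStandard, n_blocks: int) -> list[list[str]]:
    """Contiguous DEG blocks, ordered by pathway, hosting the communities.

    The two end blocks of the connector chain each take ~29 % of the DEGs so
    that every connector separates the graph into two parts larger than a
    quarter of it — the regime in which the connectors dominate the
    BottleNeck ranking by construction.
    """
    ordered: list[str] = []
    for label in PATHWAY_LABELS:
        ordered.extend(sorted(gold.genes.index[gold.genes["pathway"] == label]))
    if not ordered:
        return []
    n = len(ordered)
    if n_blocks <= 2:
        sizes = np.full(n_blocks, n // n_blocks)
        sizes[: n % n_blocks] += 1
    else:
        end = int(round(0.29 * n))
        interior = n_blocks - 2
        sizes = np.full(n_blocks, 0)
        sizes[0] = sizes[-1] = end
        rest = n - 2 * end
        sizes[1:-1] = rest // interior
        sizes[1 : 1 + rest % interior] += 1
    blocks, cursor = [], 0
    for size in sizes:
        blocks.append(ordered[cursor : cursor + int(size)])
        cursor += int(size)
    return blocks


def simulate_regulons_and_network(
    config: SimulationConfig,
    gold: GoldStandard,
    tss: pd.DataFrame,
    rng=None,
    onco_rng=None,
    reg_rng=None,
):
    """Regulon database, interaction edge list, and oncogene ChIP peaks.

    Driver TF regulons draw ``tf_pathway_purity`` of their targets from the
    driver's planted pathway.  The interaction network consists of
    preferential-attachment communities aligned with pathway blocks, wired
    in a chain through connector nodes that are each the sole link between
    adjacent communities; spoke-and-ring hubs (high MNC) and clique nodes
    (high DMNC) are embedded as the planted reduction truth.  The oncogene
    ChIP peak file carries -log10(p) >= 300 peaks exactly at the designated
    target promoters (plus sub-threshold and TSS-distal decoy peaks).
    """
    if rng is None:
        streams = _streams(config.seed)
        rng, onco_rng = streams["network"], streams["oncogene"]
        reg_rng = streams["regulons"]
    if onco_rng is None or reg_rng is None:
        raise ConfigurationError("pass all three rng streams or none")
    if config.n_tfs == 0 and config.regulon_size > 0:
        raise ConfigurationError("n_tfs=0 with nonzero regulon demand")

    genes = list(gold.genes.index)
    deg_genes = [g for g in genes if gold.genes.loc[g, "pathway"] != NO_PATHWAY]
    edges: list[tuple[str, str, str]] = []
    structural: set[str] = set()
    hubs: list[str] = []
    connectors: list[str] = []

    if deg_genes:
        n_blocks = config.n_bottleneck_connectors + 1
        blocks = _pathway_blocks(gold, n_blocks)
        ring_assign = [b % n_blocks for b in range(config.n_mnc_hubs)]
        n_cliques = int(np.ceil(config.n_dmnc_hubs / max(1, config.dmnc_clique_size)))
        clique_assign = [(b + 1) % n_blocks for b in range(n_cliques)]
        for b, block in enumerate(blocks):
            demand = sum(1 + config.mnc_ring_size for hb in ring_assign if hb == b)
            demand += sum(config.dmnc_clique_size for cb in clique_assign if cb == b)
            demand += 1 if b < n_blocks - 1 else 0  # connector
            if len(block) - demand < 5:
                raise ConfigurationError(
                    "too few DEGs per community for the planted hub/connector "
                    "structure; lower n_bottleneck_connectors or the hub sizes"
                )
        # connectors: one DEG reserved at each block boundary
        block_rest = []
        for b, block in enumerate(blocks):
            block = list(block)
            if b < len(blocks) - 1:
                connectors.append(block.pop())
            block_rest.append(block)
        structural.update(connectors)

        # engineered hubs, round-robin over blocks; structural genes are
        # drawn uniformly across each block so no single pathway is drained
        def _take(pool: list[str], k: int) -> list[str]:
            idx = sorted(rng.choice(len(pool), size=k, replace=False), reverse=True)
            return [pool.pop(i) for i in idx]

        tree_nodes: list[list[str]] = []
        ring_structs: list[tuple[str, list[str], int]] = []  # hub, members, block
        clique_structs: list[tuple[list[str], int]] = []
        for b, block in enumerate(block_rest):
            pool = list(block)
            for h, hb in enumerate(ring_assign):
                if hb == b:
                    hub, *members = _take(pool, 1 + config.mnc_ring_size)
                    ring_structs.append((hub, members, b))
                    structural.add(hub)
                    structural.update(members)
            for c, cb in enumerate(clique_assign):
                if cb == b:
                    size = min(
                        config.dmnc_clique_size,
                        config.n_dmnc_hubs - c * config.dmnc_clique_size,
                    )
                    members = _take(pool, size)
                    clique_structs.append((members, b))
                    structural.update(members)
            tree_nodes.append(pool)

        # preferential-attachment community trees
        leaves_by_block: list[list[str]] = []
        for b, pool in enumerate(tree_nodes):
            m = max(1, min(config.ppi_attachment, len(pool) - 1))
            seed_int = int(rng.integers(0, 2**31 - 1))
            ba = nx.barabasi_albert_graph(len(pool), m, seed=seed_int)
            for u, v in ba.edges():
                edges.append((pool[u], "pp", pool[v]))
            leaves_by_block.append(
                sorted(pool[u] for u in ba.nodes if ba.degree(u) == 1)
            )

        # spoke-and-ring hubs (high MNC), bridged to the community tree
        for hub, members, b in ring_structs:
            for k, member in enumerate(members):
                edges.append((hub, "pp", member))
                edges.append((member, "pp", members[(k + 1) % len(members)]))
            bridge = tree_nodes[b][int(rng.integers(0, len(tree_nodes[b])))]
            edges.append((members[0], "pp", bridge))
            hubs.append(hub)
        # cliques (high DMNC), bridged to the community tree
        for members, b in clique_structs:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    edges.append((members[i], "pp", members[j]))
            bridge = tree_nodes[b][int(rng.integers(0, len(tree_nodes[b])))]
            edges.append((members[0], "pp", bridge))
            hubs.extend(members)

        # connector chain: sole links between adjacent communities
        for c, connector in enumerate(connectors):
            for side in (c, c + 1):
                fan = rng.choice(len(tree_nodes[side]), size=min(4, len(tree_nodes[side])), replace=False)
                for idx in fan:
                    edges.append((connector, "pp", tree_nodes[side][int(idx)]))
            if c > 0:
                edges.append((connectors[c - 1], "pp", connector))

        # decoy edges touching non-DEGs (dropped at assembly)
        non_deg = [g for g in genes if gold.genes.loc[g, "pathway"] == NO_PATHWAY]
        for _ in range(max(10, config.n_genes // 40)):
            a = non_deg[int(rng.integers(0, len(non_deg)))]
            b2 = genes[int(rng.integers(0, len(genes)))]
            if a != b2:
                edges.append((a, "pp", b2))

    # regulons: within-pathway targets are community-tree leaves (mutually
    # non-adjacent, so TF fan-in edges do not manufacture spurious hubs or
    # shortcut paths in the assembled GRN); the out-of-pathway remainder is
    # drawn from non-DEG genes, which never enter the GRN.
    tf_genes = sorted(gold.genes.index[gold.genes["is_tf"] == 1])
    eligible = [g for g in genes if g not in structural]
    # a pathway's usable leaves live in one "home" community, so a TF's fan
    # of regulon edges can never bridge two communities
    leaves_by_pathway: dict[str, list[str]] = {label: [] for label in PATHWAY_LABELS}
    if deg_genes:
        pathway_of = gold.genes["pathway"]
        for label in PATHWAY_LABELS:
            counts = [
                sum(1 for g in blk if pathway_of[g] == label) for blk in blocks
            ]
            if max(counts) == 0:
                continue
            home = int(np.argmax(counts))
            leaves_by_pathway[label] = [
                g for g in leaves_by_block[home] if pathway_of[g] == label
            ]
    leaf_set = {g for pool in leaves_by_pathway.values() for g in pool}
    non_deg_pool = [g for g in eligible if gold.genes.loc[g, "pathway"] == NO_PATHWAY]
    regulons: dict[str, list[str]] = {}
    for tf in tf_genes:
        size = max(8, int(reg_rng.poisson(config.regulon_size)))
        if tf in gold.tf_pathways:
            pathway = gold.tf_pathways[tf]
            pool = leaves_by_pathway.get(pathway, [])
            n_in = min(len(pool), int(round(config.tf_pathway_purity * size)))
            inside = list(reg_rng.choice(pool, size=n_in, replace=False)) if n_in else []
            outside_pool = [g for g in non_deg_pool if g != tf]
            # the out-of-pathway remainder never dilutes purity below target
            purity = max(config.tf_pathway_purity, 0.5)
            n_out = min(len(outside_pool), size - n_in,
                        int(n_in * (1 - purity) / purity))
            outside = list(reg_rng.choice(outside_pool, size=n_out, replace=False))
            regulons[tf] = sorted(inside + outside)
        else:
            # decoys: mostly non-DEG targets plus a sprinkling of DEG leaves
            # from a single pathway's home community
            planted = [lab for lab in PATHWAY_LABELS if leaves_by_pathway[lab]]
            sprinkle: list[str] = []
            if planted:
                lab = planted[len(regulons) % len(planted)]
                pool = leaves_by_pathway[lab]
                n_leaf = min(len(pool), size // 4)
                if n_leaf:
                    sprinkle = list(reg_rng.choice(pool, size=n_leaf, replace=False))
            pool = [g for g in non_deg_pool if g != tf and g not in set(sprinkle)]
            rest = list(reg_rng.choice(pool, size=min(size - len(sprinkle), len(pool)), replace=False))
            regulons[tf] = sorted(sprinkle + rest)

    # oncogene ChIP peaks
    oncogene = ""
    onco_targets: list[str] = []
    for tf, pathway in gold.tf_pathways.items():
        if pathway == "vi":
            oncogene = tf
    if not oncogene and gold.tf_pathways:
        oncogene = sorted(gold.tf_pathways)[0]
    onco_rows = []
    if oncogene:
        # ChIP-confirmed targets are a subset of the oncogene's regulon that
        # lies in its planted pathway (direct binding at DEG promoters)
        own_pathway = gold.tf_pathways.get(oncogene, "")
        pool = [
            g for g in regulons.get(oncogene, [])
            if gold.genes.loc[g, "pathway"] == own_pathway
        ]
        n_targets = min(config.n_oncogene_targets, len(pool))
        onco_targets = sorted(onco_rng.choice(pool, size=n_targets, replace=False)) if n_targets else []
        tss_positions = tss["tss"]
        for target in onco_targets:
            summit = int(tss_positions[target] + onco_rng.integers(-500, 501))
            onco_rows.append((summit, float(onco_rng.uniform(300.0, 500.0))))
        # sub-threshold decoys at other promoters
        others = [g for g in eligible if g not in set(onco_targets)]
        weak = onco_rng.choice(others, size=min(20, len(others)), replace=False)
        for gene in weak:
            summit = int(tss_positions[gene] + onco_rng.integers(-500, 501))
            onco_rows.append((summit, float(onco_rng.uniform(50.0, 299.0))))
        # high-confidence decoys far from every promoter (mid-intergenic)
        for _ in range(10):
            idx = int(onco_rng.integers(1, config.n_genes))
            summit = idx * config.tss_spacing  # 5 kb from flanking TSSs
            onco_rows.append((summit, float(onco_rng.uniform(300.0, 500.0))))
    onco_peaks = pd.DataFrame(
        [
            (CHROM, s - 250, s + 250, f"onco_{k}", 0, ".", 10.0, p, p - 2.0, 250)
            for k, (s, p) in enumerate(sorted(onco_rows))
        ],
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "signal", "neglog10_p", "neglog10_q", "summit_offset",
        ],
    )
    if len(onco_peaks):
        onco_peaks["summit"] = onco_peaks["start"] + onco_peaks["summit_offset"]

    # CRM catalog: a mix of DEG and non-DEG chromatin factors
    crm_classes = ("writer", "eraser", "reader", "other")
    crm_pool = [g for g in eligible if gold.genes.loc[g, "is_tf"] == 0]
    crm_deg = [g for g in crm_pool if gold.genes.loc[g, "pathway"] != NO_PATHWAY]
    crm_non = [g for g in crm_pool if gold.genes.loc[g, "pathway"] == NO_PATHWAY]
    picked = list(reg_rng.choice(crm_deg, size=min(20, len(crm_deg)), replace=False))
    picked += list(reg_rng.choice(crm_non, size=min(10, len(crm_non)), replace=False))
    catalog = pd.DataFrame(
        {"crm_class": [crm_classes[k % 4] for k in range(len(picked))]},
        index=pd.Index(sorted(picked), name="gene_id"),
    )

    gold.hubs = sorted(hubs)
    gold.bottlenecks = sorted(connectors)
    gold.oncogene = oncogene
    gold.oncogene_targets = onco_targets
    return regulons, edges, onco_peaks, catalog


# ---------------------------------------------------------------------------
# orchestrator


def simulate_all(config: SimulationConfig, outdir) -> GoldStandard:
    """Generate and write the full input bundle; returns the gold standard."""
    config.validate()
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    streams = _streams(config.seed)

    log.info("simulating expression (%d genes)", config.n_genes)
    matrix, gold = simulate_expression(
        config, rng=streams["expression"], roles_rng=streams["roles"]
    )
    write_expression(matrix, outdir / "expression.tsv", outdir / "design.tsv")

    log.info("simulating chromatin tracks and peaks")
    tss, tracks, peaks = simulate_chromatin(config, gold, rng=streams["chromatin"])
    write_tss_bed(tss, outdir / "tss.bed")
    for (mark, stage), track in sorted(tracks.items()):
        write_track(track, outdir / "coverage" / f"{mark}_{stage}.bedgraph")
    for (mark, stage), frame in sorted(peaks.items()):
        write_peaks(frame, outdir / "peaks" / f"{mark}_{stage}.narrowPeak")

    log.info("simulating regulons, interaction network, oncogene peaks")
    regulons, edges, onco_peaks, catalog = simulate_regulons_and_network(
        config, gold, tss,
        rng=streams["network"], onco_rng=streams["oncogene"], reg_rng=streams["regulons"],
    )
    write_gmt(regulons, outdir / "regulons.gmt")
    write_sif(edges, outdir / "interactions.sif")
    write_peaks(onco_peaks, outdir / "oncogene_peaks.narrowPeak")
    write_crm_catalog(catalog, outdir / "crm_catalog.tsv")
    gold.write(outdir / "gold")
    return gold
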