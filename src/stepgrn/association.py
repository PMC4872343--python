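"""TF/pathway association, CRM annotation, and epigenome-transcriptome
integration.

Candidate transcription factors must cover more than 10 % of some
co-expression pathway's DEGs and carry promoter-associated RNA Pol II; their
pathway relevance is scored by an upper-tail hypergeometric test and
organized by hierarchical clustering.  Chromatin-state transition clusters
are integrated with co-expression pathways through a contingency table whose
Pearson residuals flag enriched cluster/pathway combinations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .config import NO_PATHWAY, POL2, ConfigurationError

log = logging.getLogger("stepgrn.associate")


# ---------------------------------------------------------------------------
# TF selection


def pathway_gene_sets(degs: pd.DataFrame) -> dict[str, set[str]]:
    """DEG gene ids per co-expression pathway."""
    sets: dict[str, set[str]] = {}
    for pathway, group in degs[degs["pathway"] != NO_PATHWAY].groupby("pathway"):
        sets[str(pathway)] = set(group.index)
    return sets


def select_tfs(
    regulons: dict[str, list[str]],
    degs: pd.DataFrame,
    presence: pd.DataFrame,
    min_cover: float = 0.10,
    pol2_stage: str = "any",
) -> list[str]:
    """TFs covering >min_cover of some pathway's DEGs, with Pol II at their
    own promoter.

    Coverage is |regulon ∩ pathway| / |pathway| with the pathway as the
    denominator, and the inequality is strict.  The Pol II filter requires
    presence at the TF's own TSS in at least one stage (``pol2_stage="any"``)
    or in the named stage.  TFs absent from the promoter annotation are
    excluded with a warning rather than an error.
    """
    pathways = pathway_gene_sets(degs)
    annotated = set(presence.index.get_level_values("gene_id"))
    selected = []
    for tf in sorted(regulons):
        targets = set(regulons[tf])
        covered = any(
            len(targets & genes) / len(genes) > min_cover
            for genes in pathways.values()
            if genes
        )
        if not covered:
            continue
        if tf not in annotated:
            log.warning("TF %s has no TSS annotation; excluded", tf)
            continue
        pol2 = presence.xs(tf, level="gene_id")[POL2]
        if pol2_stage != "any":
            pol2 = pol2.loc[[pol2_stage]]
        if bool(pol2.any()):
            selected.append(tf)
    return selected


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_enrichment(regulon, pathway, universe) -> float:
    """Upper-tail hypergeometric p-value for regulon/pathway overlap.

    P(X >= overlap) drawing |pathway| genes from a universe of N containing
    |regulon| successes; monotone decreasing in the overlap at fixed margins.
    """
    universe = set(universe)
    if not universe:
        raise ConfigurationError("empty gene universe")
    regulon = set(regulon) & universe
    pathway = set(pathway) & universe
    overlap = len(regulon & pathway)
    N, K, n = len(universe), len(regulon), len(pathway)
    # P(X >= k) = sf(k - 1)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def association_matrix(
    regulons: dict[str, list[str]],
    tfs,
    degs: pd.DataFrame,
    universe,
    neglog10_cap: float = 300.0,
) -> pd.DataFrame:
    """TF x pathway table of p, -log10(p) (capped), and coverage fraction.

    Returned in long form with columns tf, pathway, p, neglog10_p, coverage;
    use :func:`neglog10_pivot` for the clustering-ready wide matrix.
    """
    pathways = pathway_gene_sets(degs)
    rows = []
    for tf in sorted(tfs):
        targets = set(regulons[tf])
        for pathway in sorted(pathways):
            genes = pathways[pathway]
            p = hypergeom_enrichment(targets, genes, universe)
            neglog = min(-np.log10(max(p, 10.0 ** (-neglog10_cap))), neglog10_cap)
            coverage = len(targets & genes) / len(genes)
            rows.append((tf, pathway, p, neglog, coverage))
    return pd.DataFrame(rows, columns=["tf", "pathway", "p", "neglog10_p", "coverage"])


def neglog10_pivot(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.pivot(index="tf", columns="pathway", values="neglog10_p")


def cluster_associations(
    pivot: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
):
    """Deterministic agglomerative ordering of the association heat map.

    Average-linkage clustering on Euclidean distances between -log10(p)
    rows (and columns); returns (row_order, col_order) as index lists.
    Single-row or single-column matrices get their trivial order.
    """
    def _order(frame: pd.DataFrame) -> list:
        if frame.shape[0] < 2:
            return list(frame.index)
        link = hierarchy.linkage(pdist(frame.to_numpy(float), metric=metric), method=method)
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    return _order(pivot), _order(pivot.T)


# ---------------------------------------------------------------------------
# epigenome-transcriptome integration


def integrate_states_pathways(
    trajectories: pd.DataFrame,
    degs: pd.DataFrame,
    residual_enrichment: float = 2.0,
):
    """Contingency of transition clusters vs co-expression pathways.

    Over genes shared by both inputs (DEGs only), builds observed counts O,
    independence expectations E = row*col/total, and Pearson residuals
    (O-E)/sqrt(E); the residual sum of squares equals the chi-square
    statistic of the table.  Cells with residual above
    ``residual_enrichment`` are flagged enriched.  Degenerate tables (a
    single row or column) get all-zero residuals and a warning.
    """
    shared = trajectories.index.intersection(
        degs.index[degs["pathway"] != NO_PATHWAY]
    )
    if len(shared) == 0:
        raise ConfigurationError("no genes shared between trajectories and DEGs")
    observed = pd.crosstab(
        trajectories.loc[shared, "cluster"], degs.loc[shared, "pathway"]
    )
    observed.index.name = "cluster"
    observed.columns.name = "pathway"
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        log.warning("degenerate contingency table; residuals set to 0")
        residuals = observed.astype(float) * 0.0
        expected = observed.astype(float)
    else:
        expected = pd.DataFrame(
            stats.contingency.expected_freq(observed.to_numpy(float)),
            index=observed.index, columns=observed.columns,
        )
        residuals = (observed - expected) / np.sqrt(expected)
    enriched = residuals > residual_enrichment
    return observed, expected, residuals, enriched


# ---------------------------------------------------------------------------
# chromatin remodelers/modifiers


def annotate_crms(degs: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Differentially expressed CRMs with class and step-of-change.

    Intersects the DEG set with the CRM catalog (gene -> class in writer /
    eraser / reader / other) and reports whether expression changed at the
    first step only, the last step only, or both.
    """
    if catalog is None or len(catalog) == 0:
        log.warning("empty CRM catalog; no CRMs annotated")
        return pd.DataFrame(columns=["crm_class", "step_of_change", "pathway"])
    deg_rows = degs[degs["pathway"] != NO_PATHWAY]
    shared = deg_rows.index.intersection(catalog.index)
    out = pd.DataFrame(index=shared)
    out["crm_class"] = catalog.loc[shared, "crm_class"]
    s1 = deg_rows.loc[shared, "call_step1"] != "ns"
    s2 = deg_rows.loc[shared, "call_step2"] != "ns"
    out["step_of_change"] = np.where(
        s1 & s2, "both", np.where(s1, "step1_only", "step2_only")
    )
    out["pathway"] = deg_rows.loc[shared, "pathway"]
    out.index.name = "gene_id"
    return out.sort_index()
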