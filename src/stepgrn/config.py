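"""Configuration objects and shared constants for the stepwise-GRN pipeline.

All stage thresholds default to the values used throughout the analysis:
fold gates 2.0 / 0.5, significance 0.05, promoter window +/-500 bp, z-score
gate 1.65 (the ~95th percentile of a standard normal), subsampling dispersion
gate 15 %, transcription-factor coverage gate 10 %, oncogene ChIP confidence
gate -log10(p) >= 300, DMNC exponent 1.7.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml


class StepgrnError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(StepgrnError):
    """Invalid configuration or unusable input."""


#: Ordered cell-model stages: primary, immortalized/pre-transformed, transformed.
DEFAULT_STAGES: tuple[str, str, str] = ("baseline", "immortalized", "transformed")

#: The seven co-expression pathway labels.
PATHWAY_LABELS: tuple[str, ...] = ("i", "ii", "iii", "iv", "v", "vi", "vii")

#: Sentinel pathway for genes with no differential call.
NO_PATHWAY = "none"

#: Default mapping from the eight non-(ns,ns) per-step call patterns to the
#: seven pathway labels.  The two discordant-reversal patterns (up,down) and
#: (down,up) are merged into a single label, so 8 patterns -> 7 labels.  The
#: exact correspondence is configuration data, not code: override via
#: PipelineConfig.pattern_mapping.
DEFAULT_PATTERN_MAPPING: Mapping[tuple[str, str], str] = {
    ("up", "ns"): "i",
    ("up", "down"): "ii",
    ("down", "up"): "ii",
    ("down", "ns"): "iii",
    ("up", "up"): "iv",
    ("down", "down"): "v",
    ("ns", "up"): "vi",
    ("ns", "down"): "vii",
}

#: ChIP targets profiled at promoters.  Order matters: presence vectors and
#: state definitions index into this tuple.
MARKS: tuple[str, ...] = ("H3K4me3", "H3K9ac", "H3K27ac", "RNAPII", "H3K27me3")

#: Histone marks of active transcription (promoter-associated acetyl/methyl).
ACTIVE_MARKS: tuple[str, ...] = ("H3K4me3", "H3K9ac", "H3K27ac")

#: The repressive mark.
REPRESSIVE_MARK = "H3K27me3"

#: RNA polymerase II track name.
POL2 = "RNAPII"

#: The seven promoter chromatin states.
STATE_LABELS: tuple[str, ...] = (
    "active",
    "weakly_active",
    "transcription_prone",
    "bivalent",
    "ambiguous",
    "empty",
    "repressed",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    The defaults emulate the stepwise transformation design: three stages,
    two biological replicates each, seven planted co-expression pathways,
    promoter chromatin states correlated with expression, TF regulons driving
    pathways, and a scale-free interaction network with engineered hubs and
    bottleneck connectors.
    """

    n_genes: int = 2000
    n_tfs: int = 14
    stages: tuple[str, str, str] = DEFAULT_STAGES
    n_replicates: int = 2
    #: fraction of genes planted in each pathway; remainder are non-DEGs.
    pathway_proportions: Mapping[str, float] = field(
        default_factory=lambda: {label: 0.04 for label in PATHWAY_LABELS}
    )
    #: mean |log2 ratio| of a planted expression change.
    effect_size: float = 1.5
    #: log2-scale replicate noise standard deviation.
    noise_sd: float = 0.25
    #: probability that a planted chromatin state emits its defining marks.
    state_emission: float = 0.95
    #: mean regulon size (targets per TF).
    regulon_size: int = 30
    #: fraction of a driver TF's regulon drawn from its planted pathway.
    tf_pathway_purity: float = 0.8
    #: preferential-attachment parameter (edges per new node) of each
    #: interaction-network community.
    ppi_attachment: int = 1
    #: connector nodes inserted as sole links between network communities.
    n_bottleneck_connectors: int = 6
    #: engineered high-MNC hub nodes (spoke-and-ring neighborhoods).
    n_mnc_hubs: int = 8
    #: engineered high-DMNC nodes (members of planted cliques).
    n_dmnc_hubs: int = 8
    #: clique size used for the DMNC-engineered nodes.
    dmnc_clique_size: int = 4
    #: ring size of each MNC hub neighborhood.
    mnc_ring_size: int = 12
    #: number of oncogene ChIP target genes.
    n_oncogene_targets: int = 30
    #: genomic spacing between consecutive TSSs (bp); >=10 kb so +/-1.5 kb
    #: windows never overlap.
    tss_spacing: int = 10_000
    #: coverage bin width (bp).
    bin_size: int = 100
    seed: int = 0

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 0, **overrides) -> "SimulationConfig":
        """Config with planted network structure sized to fit ``n_genes``.

        The stock defaults assume ~560 DEGs; smaller toy genomes get
        proportionally fewer/smaller hubs, cliques, and connectors.
        """
        if n_genes >= 1500:
            structure = {}
        elif n_genes >= 600:
            structure = dict(n_bottleneck_connectors=2, n_mnc_hubs=4,
                             mnc_ring_size=6, n_dmnc_hubs=4, dmnc_clique_size=4)
        else:
            structure = dict(n_bottleneck_connectors=1, n_mnc_hubs=2,
                             mnc_ring_size=4, n_dmnc_hubs=4, dmnc_clique_size=4,
                             n_oncogene_targets=10)
        structure.update(overrides)
        return cls(n_genes=n_genes, seed=seed, **structure)

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "n_replicates", "tss_spacing", "bin_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if len(self.stages) != 3:
            raise ConfigurationError("exactly three stages are required")
        total = float(sum(self.pathway_proportions.values()))
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"pathway proportions sum to {total:.3f} > 1"
            )
        for label, frac in self.pathway_proportions.items():
            if label not in PATHWAY_LABELS:
                raise ConfigurationError(f"unknown pathway label {label!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"proportion for {label!r} outside [0,1]")
        if not 0.0 <= self.state_emission <= 1.0:
            raise ConfigurationError("state_emission outside [0,1]")
        if self.tss_spacing < 4 * 1500:
            raise ConfigurationError("tss_spacing too small for +/-1.5 kb windows")


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths, serializable to YAML."""

    # expression stage
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    #: prior degrees of freedom for variance moderation in the DEG test;
    #: 0 disables moderation (plain Welch t).
    var_prior_df: float = 8.0
    #: apply Benjamini-Hochberg correction to the per-step p-values.
    bh_correct: bool = False
    pattern_mapping: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MAPPING)
    )

    # chromatin stage
    window: int = 500
    zmin: float = 1.65
    max_dispersion: float = 0.15
    subsample_fractions: tuple[float, ...] = (0.9, 0.7, 0.5)
    subsample_reps: int = 5
    profile_flank: int = 1500
    #: classify H3K27me3 plus any active evidence as bivalent; if False such
    #: combinations fall back to "ambiguous".
    bivalent_closure: bool = True

    # association stage
    min_cover: float = 0.10
    #: which stages may satisfy the Pol II filter ("any" or a stage name).
    pol2_stage: str = "any"
    neglog10_cap: float = 300.0
    linkage_method: str = "average"
    linkage_metric: str = "euclidean"
    residual_enrichment: float = 2.0

    # network stage
    minlogp: float = 300.0
    epsilon: float = 1.7
    promoter_window: int = 1000
    k_hubs: int = 8
    k_bottlenecks: int = 6

    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["pattern_mapping"] = {
            f"{a},{b}": lab for (a, b), lab in self.pattern_mapping.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "pattern_mapping" in payload:
            payload["pattern_mapping"] = {
                tuple(key.split(",")): lab
                for key, lab in payload["pattern_mapping"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for name in ("subsample_fractions",):
            if name in payload and payload[name] is not None:
                payload[name] = tuple(payload[name])
        return cls(**payload)
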