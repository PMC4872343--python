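"""Readers and writers for the line-oriented formats the pipeline consumes.

Everything is plain TSV in community conventions: expression matrices with a
sample-design sheet, BED6 TSS annotation, narrowPeak-like peak calls (summit
column optional: -1 or a missing column falls back to the interval midpoint),
bedGraph-like binned coverage, GMT regulon files, and SIF edge lists.  All
genomic coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "neglog10_p", "neglog10_q", "summit_offset",
]


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with a sample -> (stage, replicate) map.

    ``values`` holds non-negative, log2-transformable abundances on the linear
    scale; ``design`` is indexed by sample name with columns ``stage`` and
    ``replicate``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def validate(self, stages) -> None:
        if self.values.index.duplicated().any():
            raise ConfigurationError("duplicate gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ConfigurationError(f"samples without design rows: {sorted(missing)}")
        for stage in stages:
            n = int((self.design["stage"] == stage).sum())
            if n == 0:
                raise ConfigurationError(f"stage {stage!r} missing from design")
            if n < 2:
                raise ConfigurationError(f"stage {stage!r} has fewer than 2 replicates")
        if (self.values.values < 0).any():
            raise ConfigurationError("negative abundances in expression matrix")

    def stage_columns(self, stage: str) -> list[str]:
        cols = self.design.index[self.design["stage"] == stage]
        return [c for c in self.values.columns if c in set(cols)]

    def stage_values(self, stage: str) -> np.ndarray:
        return self.values[self.stage_columns(stage)].to_numpy(float)


def write_expression(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id", float_format="%.4f")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample")


def read_expression(matrix_path, design_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values=values, design=design)


# ---------------------------------------------------------------------------
# TSS annotation (BED6)


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    """``tss``: index gene_id, columns chrom, tss (position), strand."""
    start = tss["tss"].to_numpy(int)
    bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": start,
            "end": start + 1,
            "name": tss.index,
            "score": 0,
            "strand": tss["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if bed["name"].duplicated().any():
        raise ConfigurationError("duplicate gene ids in TSS annotation")
    out = pd.DataFrame(
        {"chrom": bed["chrom"].values, "tss": bed["start"].values, "strand": bed["strand"].values},
        index=pd.Index(bed["name"], name="gene_id"),
    )
    return out


# ---------------------------------------------------------------------------
# peaks (narrowPeak dialect; summit optional)


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", header=False, index=False,
                 columns=NARROWPEAK_COLUMNS, float_format="%.4f")


def read_peaks(path) -> pd.DataFrame:
    """Accepts 6-10 column narrowPeak/broadPeak-like TSVs.

    A missing or negative summit-offset column yields the interval midpoint.
    """
    peaks = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = peaks.shape[1]
    if ncol < 3:
        raise ConfigurationError(f"peak file {path} has fewer than 3 columns")
    peaks.columns = NARROWPEAK_COLUMNS[:ncol]
    for col, default in (
        ("name", "."), ("score", 0), ("strand", "."),
        ("signal", np.nan), ("neglog10_p", np.nan), ("neglog10_q", np.nan),
        ("summit_offset", -1),
    ):
        if col not in peaks.columns:
            peaks[col] = default
    summit = peaks["start"] + peaks["summit_offset"].astype(int)
    midpoint = (peaks["start"] + peaks["end"]) // 2
    peaks["summit"] = np.where(peaks["summit_offset"].astype(int) >= 0, summit, midpoint)
    return peaks


# ---------------------------------------------------------------------------
# binned coverage (bedGraph-like, uniform non-overlapping grid)


@dataclass
class BinnedTrack:
    """Intensity per non-overlapping fixed-width bin on a single chromosome."""

    target: str
    stage: str
    chrom: str
    bin_size: int
    starts: np.ndarray
    values: np.ndarray
    status: str = "raw"  # raw | quantile | z

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.starts.shape != self.values.shape:
            raise ConfigurationError("bin grid and values differ in length")
        if len(self.starts) > 1:
            step = np.diff(self.starts)
            if (step < self.bin_size).any():
                raise ConfigurationError("overlapping bins in coverage track")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("non-finite intensities in coverage track")

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and len(self.starts) == len(other.starts)
            and bool(np.array_equal(self.starts, other.starts))
        )

    def bin_index(self, position: int) -> int:
        idx = int(np.searchsorted(self.starts, position, side="right") - 1)
        if idx < 0 or position >= self.starts[idx] + self.bin_size:
            raise ConfigurationError(f"position {position} outside track grid")
        return idx


def write_track(track: BinnedTrack, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.starts,
            "end": track.starts + track.bin_size,
            "value": track.values,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def read_track(path, target: str, stage: str) -> BinnedTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ConfigurationError("multi-chromosome tracks are not supported")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ConfigurationError("non-uniform bin widths in coverage track")
    return BinnedTrack(
        target=target, stage=stage, chrom=str(chroms[0]), bin_size=int(widths[0]),
        starts=df["start"].to_numpy(np.int64), values=df["value"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# regulons (GMT-like) and CRM catalog


def write_gmt(regulons: dict[str, list[str]], path, description: str = "regulon") -> None:
    with open(path, "w") as fh:
        for tf in sorted(regulons):
            targets = "\t".join(regulons[tf])
            fh.write(f"{tf}\t{description}\t{targets}\n")


def read_gmt(path) -> dict[str, list[str]]:
    regulons: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            tf, _desc, targets = parts[0], parts[1], parts[2:]
            targets = [t for t in targets if t]
            if not targets:
                raise ConfigurationError(f"empty regulon for {tf!r}")
            regulons[tf] = targets
    return regulons


def write_crm_catalog(catalog: pd.DataFrame, path) -> None:
    """``catalog``: index gene_id, column ``crm_class``."""
    catalog.to_csv(path, sep="\t", index_label="gene_id")


def read_crm_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# interaction edge lists (SIF)


def write_sif(edges, path) -> None:
    """``edges``: iterable of (source, relation, target)."""
    with open(path, "w") as fh:
        for src, rel, dst in edges:
            fh.write(f"{src}\t{rel}\t{dst}\n")


def read_sif(path) -> list[tuple[str, str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            src, rel = parts[0], parts[1]
            for dst in parts[2:]:
                if dst:
                    edges.append((src, rel, dst))
    return edges


# ---------------------------------------------------------------------------
# gold standard


@dataclass
class GoldStandard:
    """Planted truth of a synthetic dataset.

    ``genes``: index gene_id, columns pathway, state_<stage> per stage,
    is_tf.  ``tf_pathways``: driver TF -> planted pathway.  ``hubs`` /
    ``bottlenecks``: engineered node id lists.  ``oncogene_targets``: the
    designated high-confidence oncogene ChIP target genes.
    """

    genes: pd.DataFrame
    tf_pathways: dict[str, str] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)
    bottlenecks: list[str] = field(default_factory=list)
    oncogene: str = ""
    oncogene_targets: list[str] = field(default_factory=list)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(directory / "gold_genes.tsv", sep="\t", index_label="gene_id")
        rows = []
        for tf, pw in sorted(self.tf_pathways.items()):
            rows.append(("driver_tf", tf, pw))
        for node in self.hubs:
            rows.append(("hub", node, ""))
        for node in self.bottlenecks:
            rows.append(("bottleneck", node, ""))
        if self.oncogene:
            rows.append(("oncogene", self.oncogene, ""))
        for node in self.oncogene_targets:
            rows.append(("oncogene_target", node, ""))
        pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
            directory / "gold_nodes.tsv", sep="\t", index=False
        )

    @classmethod
    def read(cls, directory) -> "GoldStandard":
        directory = Path(directory)
        genes = pd.read_csv(directory / "gold_genes.tsv", sep="\t", index_col="gene_id")
        nodes = pd.read_csv(directory / "gold_nodes.tsv", sep="\t", keep_default_na=False)
        gold = cls(genes=genes)
        for _, row in nodes.iterrows():
            kind, node, value = row["kind"], row["id"], row["value"]
            if kind == "driver_tf":
                gold.tf_pathways[node] = value
            elif kind == "hub":
                gold.hubs.append(node)
            elif kind == "bottleneck":
                gold.bottlenecks.append(node)
            elif kind == "oncogene":
                gold.oncogene = node
            elif kind == "oncogene_target":
                gold.oncogene_targets.append(node)
        return gold
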