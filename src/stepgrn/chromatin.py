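"""Promoter chromatin-state calling and transition clustering.

ChIP signal handling follows the three-criterion presence rule: a mark is
"present" at a TSS when (i) a peak summit lies within +/-500 bp of the TSS,
(ii) the quantile- and z-normalized peak intensity exceeds z = 1.65 (the
~95th percentile), and (iii) the peak intensity is robust to subsampling
(coefficient of variation below 15 %).  The five presence bits (H3K4me3,
H3K9ac, H3K27ac, RNA Pol II, H3K27me3) classify each promoter into one of
seven chromatin states, and the ordered state triple across the three stages
defines its transition cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ACTIVE_MARKS,
    MARKS,
    POL2,
    REPRESSIVE_MARK,
    STATE_LABELS,
    ConfigurationError,
)
from .io import BinnedTrack

log = logging.getLogger("stepgrn.chromatin")

#: Canonical mark set emitted by each state in the synthetic generator; each
#: set classifies back to its own state (see classify_state).
STATE_DEFINING_MARKS: dict[str, tuple[str, ...]] = {
    "active": ("H3K4me3", "H3K9ac", "H3K27ac", "RNAPII"),
    "weakly_active": ("H3K4me3", "RNAPII"),
    "transcription_prone": ("H3K4me3", "H3K9ac"),
    "bivalent": ("H3K4me3", "H3K9ac", "H3K27ac", "RNAPII", "H3K27me3"),
    "ambiguous": ("H3K4me3",),
    "empty": (),
    "repressed": ("H3K27me3",),
}

TRAJECTORY_SEP = ">"


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Rank-mean quantile normalization across samples of one target.

    Read-count intensities are sorted and ranked per sample and the values at
    corresponding ranks are replaced by their cross-sample mean; tied values
    receive the mean of the tied ranks' reference values.  Afterwards all
    samples share the same sorted intensity multiset (up to tie averaging).
    """
    if len(tracks) < 2:
        raise ConfigurationError("quantile normalization needs >=2 tracks")
    first = tracks[0]
    for other in tracks[1:]:
        if not first.same_grid(other):
            raise ConfigurationError("mismatched bin grids across tracks")
    data = np.stack([t.values for t in tracks])
    reference = np.sort(data, axis=1).mean(axis=0)
    out = []
    for track in tracks:
        order = np.argsort(track.values, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over tied input values
        series = pd.Series(assigned)
        normalized = series.groupby(track.values).transform("mean").to_numpy()
        out.append(
            BinnedTrack(
                target=track.target, stage=track.stage, chrom=track.chrom,
                bin_size=track.bin_size, starts=track.starts.copy(),
                values=normalized, status="quantile",
            )
        )
    return out


def zscore_scale(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Bring normalized tracks of different targets to a common scale.

    Each track is transformed to mean 0 and standard deviation 1, so the
    z > 1.65 presence gate corresponds to the empirical ~95th percentile on
    normal-like tracks.
    """
    out = []
    for track in tracks:
        sd = track.values.std()
        if sd == 0.0:
            raise ConfigurationError(
                f"zero-variance track {track.target}/{track.stage}"
            )
        out.append(
            BinnedTrack(
                target=track.target, stage=track.stage, chrom=track.chrom,
                bin_size=track.bin_size, starts=track.starts.copy(),
                values=(track.values - track.values.mean()) / sd, status="z",
            )
        )
    return out


# ---------------------------------------------------------------------------
# robustness to subsampling


def subsample_dispersion(
    counts,
    fractions=(0.9, 0.7, 0.5),
    reps: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Coefficient of variation of recovered peak intensity under subsampling.

    ``counts`` are the raw per-bin read counts across the peak footprint.
    Each subsample thins the counts binomially at the stated fraction and
    rescales; the dispersion is sd/mean of the recovered totals across all
    subsamples, expressed as a fraction.  Deterministic given ``rng``.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or counts.sum() <= 0:
        raise ConfigurationError("empty coverage at peak")
    if np.issubdtype(counts.dtype, np.floating):
        counts = np.rint(counts).astype(np.int64)
    if rng is None:
        rng = np.random.default_rng(0)
    recovered = []
    for fraction in fractions:
        for _ in range(reps):
            thinned = rng.binomial(counts, fraction)
            recovered.append(thinned.sum() / fraction)
    recovered = np.asarray(recovered, dtype=float)
    mean = recovered.mean()
    if mean == 0.0:
        return float("inf")
    return float(recovered.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# peak evidence and presence calling


@dataclass
class PeakEvidence:
    """Per-peak normalized evidence used by the presence criteria."""

    target: str
    stage: str
    summit: int
    z: float
    dispersion: float


def compute_peak_evidence(
    peaks: pd.DataFrame,
    raw_track: BinnedTrack,
    z_track: BinnedTrack,
    fractions=(0.9, 0.7, 0.5),
    reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a z-score and a subsampling dispersion to every peak call.

    The z-score is the z-normalized intensity of the summit bin; the
    dispersion comes from binomial thinning of the raw counts across the
    peak interval.  Subsampling randomness is seeded per peak so evidence is
    reproducible regardless of evaluation order.
    """
    rows = []
    for idx, peak in enumerate(peaks.itertuples(index=False)):
        summit = int(peak.summit)
        z = float(z_track.values[z_track.bin_index(summit)])
        lo = raw_track.bin_index(max(int(peak.start), int(raw_track.starts[0])))
        hi = raw_track.bin_index(
            min(int(peak.end) - 1, int(raw_track.starts[-1]) + raw_track.bin_size - 1)
        )
        counts = raw_track.values[lo : hi + 1]
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        try:
            dispersion = subsample_dispersion(counts, fractions, reps, rng)
        except ConfigurationError:
            dispersion = float("inf")
        rows.append((raw_track.target, raw_track.stage, summit, z, dispersion))
    return pd.DataFrame(rows, columns=["target", "stage", "summit", "z", "dispersion"])


def call_presence(
    evidence: pd.DataFrame,
    tss: pd.DataFrame,
    stages,
    window: int = 500,
    zmin: float = 1.65,
    max_dispersion: float = 0.15,
    genes=None,
) -> pd.DataFrame:
    """Gene x stage x mark presence matrix from per-peak evidence.

    A mark is present iff some peak satisfies all three criteria: summit
    within ``window`` bp of the TSS (both boundaries inclusive), z strictly
    above ``zmin``, dispersion strictly below ``max_dispersion``.  The window
    is symmetric, so gene strand affects only the sign of reported offsets.
    """
    if genes is None:
        genes = list(tss.index)
    else:
        missing = [g for g in genes if g not in tss.index]
        if missing:
            raise ConfigurationError(f"genes without TSS annotation: {missing[:5]}")
    positions = tss.loc[genes, "tss"].to_numpy(np.int64)

    index = pd.MultiIndex.from_product([genes, list(stages)], names=["gene_id", "stage"])
    presence = pd.DataFrame(False, index=index, columns=list(MARKS))
    for (target, stage), group in evidence.groupby(["target", "stage"], sort=True):
        if target not in MARKS:
            raise ConfigurationError(f"unknown ChIP target {target!r}")
        passing = group[(group["z"] > zmin) & (group["dispersion"] < max_dispersion)]
        if len(passing) == 0:
            continue
        summits = np.sort(passing["summit"].to_numpy(np.int64))
        lo = np.searchsorted(summits, positions - window, side="left")
        hi = np.searchsorted(summits, positions + window, side="right")
        hit = hi > lo
        presence.loc[(slice(None), stage), target] = hit
    return presence


# ---------------------------------------------------------------------------
# chromatin-state taxonomy


def classify_state(presence, bivalent_closure: bool = True) -> str:
    """Classify one promoter's five presence bits into a chromatin state.

    ``presence`` maps mark name to bool (or is a 5-sequence in MARKS order).
    With A = number of active marks, P = Pol II, R = H3K27me3:

    * R absent: ``active`` if P and A>=2; ``weakly_active`` if P and A==1;
      ``transcription_prone`` if not P and A>=2; ``ambiguous`` if exactly one
      active mark or Pol II alone; ``empty`` otherwise.
    * R present: ``repressed`` when nothing else is there; any active-state
      evidence makes it ``bivalent``.  Combinations with H3K27me3 plus only
      weak evidence (one active mark alone, or Pol II alone) are classed
      ``bivalent`` by default; ``bivalent_closure=False`` sends them to
      ``ambiguous`` instead.

    Total on all 32 combinations; exactly seven labels exist.
    """
    if not isinstance(presence, dict):
        presence = dict(zip(MARKS, presence))
    active = sum(bool(presence.get(mark, False)) for mark in ACTIVE_MARKS)
    pol2 = bool(presence.get(POL2, False))
    repressive = bool(presence.get(REPRESSIVE_MARK, False))

    if pol2 and active >= 2:
        base = "active"
    elif pol2 and active == 1:
        base = "weakly_active"
    elif not pol2 and active >= 2:
        base = "transcription_prone"
    elif (not pol2 and active == 1) or (pol2 and active == 0):
        base = "ambiguous"
    else:
        base = "empty"

    if not repressive:
        return base
    if base == "empty":
        return "repressed"
    if base == "ambiguous" and not bivalent_closure:
        return "ambiguous"
    return "bivalent"


def state_trajectories(
    presence: pd.DataFrame, stages, bivalent_closure: bool = True
) -> pd.DataFrame:
    """Per-gene ordered state triple across stages plus its cluster id.

    The transition-cluster id is the triple itself (``state1>state2>state3``);
    at most 343 clusters are possible for 7 states over 3 stages.
    """
    genes = presence.index.get_level_values("gene_id").unique()
    records = {}
    for gene in genes:
        states = []
        for stage in stages:
            try:
                bits = presence.loc[(gene, stage)]
            except KeyError:
                raise ConfigurationError(f"gene {gene!r} missing stage {stage!r}")
            states.append(classify_state(dict(bits), bivalent_closure))
        records[gene] = states
    out = pd.DataFrame.from_dict(
        records, orient="index", columns=[f"state_{s}" for s in stages]
    )
    out.index.name = "gene_id"
    out["cluster"] = out.apply(TRAJECTORY_SEP.join, axis=1)
    return out


def cluster_census(trajectories: pd.DataFrame) -> pd.Series:
    """Gene counts per observed transition cluster, largest first."""
    census = trajectories["cluster"].value_counts()
    census.index.name = "cluster"
    census.name = "n_genes"
    return census


# ---------------------------------------------------------------------------
# display profiles


def median_profile(
    genes,
    tracks: dict[tuple[str, str], BinnedTrack],
    tss: pd.DataFrame,
    flank: int = 1500,
) -> pd.DataFrame:
    """Per-mark, per-stage median z-scaled signal around the TSS of a cluster.

    Rows are (target, stage); columns are bin offsets relative to the TSS,
    oriented 5'->3' by gene strand.  Medians are taken per 100-bp bin across
    the cluster's genes.
    """
    genes = list(genes)
    if not genes:
        raise ConfigurationError("median_profile: empty cluster")
    missing = [g for g in genes if g not in tss.index]
    if missing:
        raise ConfigurationError(f"genes without TSS annotation: {missing[:5]}")
    rows = {}
    offsets = None
    for (target, stage), track in sorted(tracks.items()):
        half = flank // track.bin_size
        if offsets is None:
            offsets = [(i - half) * track.bin_size for i in range(2 * half)]
        signals = []
        for gene in genes:
            center = track.bin_index(int(tss.loc[gene, "tss"]))
            lo, hi = center - half, center + half
            if lo < 0 or hi > len(track.values):
                raise ConfigurationError(f"profile window out of track bounds for {gene}")
            window = track.values[lo:hi]
            if tss.loc[gene, "strand"] == "-":
                window = window[::-1]
            signals.append(window)
        rows[(target, stage)] = np.median(np.stack(signals), axis=0)
    profile = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    profile.index = pd.MultiIndex.from_tuples(profile.index, names=["target", "stage"])
    return profile


# ---------------------------------------------------------------------------
# serialization


def write_presence(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, sep="\t")


def read_presence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=["gene_id", "stage"])
    return df.astype(bool)


def write_trajectories(trajectories: pd.DataFrame, path) -> None:
    trajectories.to_csv(path, sep="\t", index_label="gene_id")


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
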