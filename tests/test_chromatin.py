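"""Chromatin signal normalization, presence criteria, state taxonomy, and
transition clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepgrn.chromatin import (
    STATE_DEFINING_MARKS,
    call_presence,
    classify_state,
    cluster_census,
    median_profile,
    quantile_normalize,
    state_trajectories,
    subsample_dispersion,
    zscore_scale,
)
from stepgrn.config import MARKS, STATE_LABELS, ConfigurationError
from stepgrn.io import BinnedTrack

STAGES = ("baseline", "immortalized", "transformed")


def _track(values, target="H3K4me3", stage="baseline", status="raw"):
    values = np.asarray(values, dtype=float)
    return BinnedTrack(
        target=target, stage=stage, chrom="chrS", bin_size=100,
        starts=np.arange(len(values)) * 100, values=values, status=status,
    )


class TestQuantileNormalize:
    def test_rank_means_forced(self):
        a, b = _track([1, 2, 3]), _track([4, 5, 6], stage="immortalized")
        out = quantile_normalize([a, b])
        for track in out:
            assert track.values == pytest.approx([2.5, 3.5, 4.5])

    def test_fixed_point_on_identical_pair(self):
        a = _track([3, 1, 2])
        b = _track([3, 1, 2], stage="immortalized")
        out = quantile_normalize([a, b])
        assert out[0].values == pytest.approx([3, 1, 2])
        assert out[1].values == pytest.approx([3, 1, 2])

    def test_sorted_multisets_equal_and_means_match(self):
        rng = np.random.default_rng(3)
        tracks = [
            _track(rng.gamma(2, 2, 500), stage=s) for s in STAGES
        ]
        out = quantile_normalize(tracks)
        sorted_ref = np.sort(out[0].values)
        for track in out[1:]:
            assert np.sort(track.values) == pytest.approx(sorted_ref)
        means = [t.values.mean() for t in out]
        assert means == pytest.approx([means[0]] * 3)

    def test_idempotent(self):
        # exact on tie-free data; tied values are tie-averaged, which is
        # only approximately idempotent
        rng = np.random.default_rng(4)
        tracks = [_track(rng.gamma(2.0, 2.0, 300), stage=s) for s in STAGES]
        once = quantile_normalize(tracks)
        twice = quantile_normalize(once)
        for t1, t2 in zip(once, twice):
            assert t2.values == pytest.approx(t1.values)

    def test_permutation_equivariant_across_samples(self):
        rng = np.random.default_rng(5)
        tracks = [_track(rng.gamma(2, 2, 200), stage=s) for s in STAGES]
        forward = quantile_normalize(tracks)
        backward = quantile_normalize(tracks[::-1])
        for t1, t2 in zip(forward, backward[::-1]):
            assert t2.values == pytest.approx(t1.values)

    def test_mismatched_grids_error(self):
        a, b = _track([1, 2, 3]), _track([1, 2], stage="immortalized")
        with pytest.raises(ConfigurationError):
            quantile_normalize([a, b])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.lists(
                st.floats(0, 1e4, allow_subnormal=False),
                min_size=8, max_size=8, unique=True,
            ),
            min_size=2, max_size=4,
        )
    )
    def test_sorted_multisets_property(self, data):
        """On tie-free samples, rank-mean normalization equalizes the
        per-sample sorted multisets and preserves each sample's ranks."""
        tracks = [_track(v, stage=f"s{k}") for k, v in enumerate(data)]
        out = quantile_normalize(tracks)
        ref = np.sort(out[0].values)
        for before, after in zip(tracks, out):
            assert np.sort(after.values) == pytest.approx(ref, rel=1e-9, abs=1e-9)
            order = np.argsort(before.values, kind="mergesort")
            assert (np.diff(after.values[order]) >= -1e-9).all()


class TestZScore:
    def test_mean_zero_sd_one(self):
        track = _track(np.random.default_rng(0).gamma(2, 2, 400))
        (out,) = zscore_scale([track])
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0)

    def test_location_scale_invariance(self):
        base = np.random.default_rng(1).normal(5, 2, 300)
        t1, t2 = _track(base), _track(3.0 * base + 10.0, stage="immortalized")
        z1, z2 = zscore_scale([t1, t2])
        assert z2.values == pytest.approx(z1.values)

    def test_zero_variance_errors(self):
        with pytest.raises(ConfigurationError):
            zscore_scale([_track(np.ones(10))])

    def test_gaussian_tail_above_165(self):
        values = np.random.default_rng(2).normal(0, 1, 200_000)
        (out,) = zscore_scale([_track(values)])
        frac = float((out.values > 1.65).mean())
        assert frac == pytest.approx(0.0495, abs=0.004)


class TestSubsampleDispersion:
    def test_large_counts_near_zero(self):
        counts = np.full(5, 100_000)
        d = subsample_dispersion(counts, rng=np.random.default_rng(0))
        assert d < 0.01

    def test_deterministic_under_seed(self):
        counts = np.random.default_rng(1).poisson(10, 5)
        d1 = subsample_dispersion(counts, rng=np.random.default_rng(7))
        d2 = subsample_dispersion(counts, rng=np.random.default_rng(7))
        assert d1 == d2

    def test_deeper_signal_never_less_robust(self):
        counts = np.random.default_rng(2).poisson(20, 5)
        shallow = subsample_dispersion(counts, reps=40, rng=np.random.default_rng(3))
        deep = subsample_dispersion(counts * 50, reps=40, rng=np.random.default_rng(3))
        assert deep <= shallow * 1.05

    def test_matches_resampling_oracle(self):
        """Implementation CV matches an independent large-replicate
        binomial-thinning estimate within Monte-Carlo error."""
        counts = np.random.default_rng(4).poisson(10, 5)
        impl = subsample_dispersion(
            counts, fractions=(0.9, 0.7, 0.5), reps=400,
            rng=np.random.default_rng(5),
        )
        oracle_rng = np.random.default_rng(6)
        recovered = []
        for f in (0.9, 0.7, 0.5):
            for _ in range(400):
                thinned = sum(oracle_rng.binomial(int(c), f) for c in counts)
                recovered.append(thinned / f)
        recovered = np.asarray(recovered)
        oracle = recovered.std(ddof=1) / recovered.mean()
        assert impl == pytest.approx(oracle, abs=0.01)

    def test_empty_coverage_errors(self):
        with pytest.raises(ConfigurationError):
            subsample_dispersion(np.zeros(4))


def _evidence(rows):
    return pd.DataFrame(rows, columns=["target", "stage", "summit", "z", "dispersion"])


def _tss(genes, positions, strands=None):
    return pd.DataFrame(
        {"chrom": "chrS", "tss": positions,
         "strand": strands or ["+"] * len(genes)},
        index=pd.Index(genes, name="gene_id"),
    )


class TestCallPresence:
    tss = _tss(["gA"], [10_000])

    @pytest.mark.parametrize(
        "summit,z,dispersion,expected",
        [
            (10_400, 2.0, 0.10, True),   # all three criteria met
            (10_600, 3.0, 0.05, False),  # summit outside +/-500
            (9_900, 1.0, 0.05, False),   # z too low
            (10_100, 2.5, 0.20, False),  # dispersion too high
            (10_500, 2.0, 0.10, True),   # boundary position inclusive
        ],
    )
    def test_three_criteria(self, summit, z, dispersion, expected):
        evidence = _evidence([("H3K4me3", "baseline", summit, z, dispersion)])
        presence = call_presence(evidence, self.tss, STAGES)
        assert bool(presence.loc[("gA", "baseline"), "H3K4me3"]) is expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        evidence = _evidence(
            [
                ("H3K4me3", "baseline", int(10_000 + rng.integers(-800, 800)),
                 float(rng.uniform(0, 4)), float(rng.uniform(0, 0.3)))
                for _ in range(60)
            ]
        )
        loose = call_presence(evidence, self.tss, STAGES, window=500, zmin=1.65)
        strict_z = call_presence(evidence, self.tss, STAGES, window=500, zmin=2.5)
        strict_w = call_presence(evidence, self.tss, STAGES, window=200, zmin=1.65)
        assert not (strict_z & ~loose).any().any()
        assert not (strict_w & ~loose).any().any()

    def test_unannotated_gene_errors(self):
        with pytest.raises(ConfigurationError):
            call_presence(_evidence([]), self.tss, STAGES, genes=["gMissing"])


class TestClassifyState:
    def test_exhaustive_partition(self):
        """All 32 presence combinations map onto exactly the 7 states."""
        seen = {}
        for bits in itertools.product([False, True], repeat=5):
            state = classify_state(dict(zip(MARKS, bits)))
            assert state in STATE_LABELS
            seen.setdefault(state, []).append(bits)
        assert set(seen) == set(STATE_LABELS)
        assert sum(len(v) for v in seen.values()) == 32

    @pytest.mark.parametrize(
        "bits,expected",
        [
            ((1, 1, 0, 1, 0), "active"),
            ((1, 0, 0, 1, 0), "weakly_active"),
            ((1, 1, 0, 0, 0), "transcription_prone"),
            ((1, 1, 0, 1, 1), "bivalent"),
            ((1, 0, 0, 0, 0), "ambiguous"),
            ((0, 0, 0, 1, 0), "ambiguous"),
            ((0, 0, 0, 0, 0), "empty"),
            ((0, 0, 0, 0, 1), "repressed"),
        ],
    )
    def test_definitions(self, bits, expected):
        assert classify_state(bits) == expected

    def test_bivalent_closure_switch(self):
        # one active mark + H3K27me3: bivalent by default, ambiguous when
        # the closure is off
        bits = (1, 0, 0, 0, 1)
        assert classify_state(bits) == "bivalent"
        assert classify_state(bits, bivalent_closure=False) == "ambiguous"
        # Pol II alone + H3K27me3 behaves the same way
        bits = (0, 0, 0, 1, 1)
        assert classify_state(bits) == "bivalent"
        assert classify_state(bits, bivalent_closure=False) == "ambiguous"

    def test_defining_marks_classify_to_own_state(self):
        for state, marks in STATE_DEFINING_MARKS.items():
            bits = {m: m in marks for m in MARKS}
            assert classify_state(bits) == state


class TestTrajectories:
    def _presence(self, genes, state_marks):
        index = pd.MultiIndex.from_product([genes, STAGES], names=["gene_id", "stage"])
        presence = pd.DataFrame(False, index=index, columns=list(MARKS))
        for gene in genes:
            for stage in STAGES:
                for mark in state_marks[(gene, stage)]:
                    presence.loc[(gene, stage), mark] = True
        return presence

    def test_constant_active_single_cluster(self):
        genes = ["g1", "g2", "g3"]
        marks = {(g, s): STATE_DEFINING_MARKS["active"] for g in genes for s in STAGES}
        trajectories = state_trajectories(self._presence(genes, marks), STAGES)
        census = cluster_census(trajectories)
        assert len(census) == 1
        assert census.iloc[0] == 3
        assert census.index[0] == "active>active>active"

    def test_bivalent_resolution_trajectory(self):
        # a poised promoter resolving to full activity after immortalization
        marks = {("g", STAGES[0]): STATE_DEFINING_MARKS["bivalent"],
                 ("g", STAGES[1]): STATE_DEFINING_MARKS["active"],
                 ("g", STAGES[2]): STATE_DEFINING_MARKS["active"]}
        trajectories = state_trajectories(self._presence(["g"], marks), STAGES)
        assert trajectories.loc["g", "cluster"] == "bivalent>active>active"

    def test_missing_stage_errors(self):
        index = pd.MultiIndex.from_tuples(
            [("g", STAGES[0]), ("g", STAGES[1])], names=["gene_id", "stage"]
        )
        presence = pd.DataFrame(False, index=index, columns=list(MARKS))
        with pytest.raises(ConfigurationError):
            state_trajectories(presence, STAGES)


class TestMedianProfile:
    def _tracks(self, n_bins=200, seed=0):
        rng = np.random.default_rng(seed)
        return {
            (m, s): _track(rng.normal(0, 1, n_bins), target=m, stage=s, status="z")
            for m in MARKS[:2] for s in STAGES
        }

    def test_single_gene_equals_own_signal(self):
        tracks = self._tracks()
        tss = _tss(["g"], [10_000])
        profile = median_profile(["g"], tracks, tss, flank=500)
        track = tracks[("H3K4me3", "baseline")]
        center = 100
        expected = track.values[center - 5 : center + 5]
        assert profile.loc[("H3K4me3", "baseline")].to_numpy() == pytest.approx(expected)

    def test_minus_strand_reverses(self):
        tracks = self._tracks()
        plus = median_profile(["g"], tracks, _tss(["g"], [10_000]), flank=500)
        minus = median_profile(["g"], tracks, _tss(["g"], [10_000], ["-"]), flank=500)
        assert minus.loc[("H3K4me3", "baseline")].to_numpy() == pytest.approx(
            plus.loc[("H3K4me3", "baseline")].to_numpy()[::-1]
        )

    def test_median_robust_to_opposite_outlier_pair(self):
        tracks = self._tracks()
        genes = [f"g{i}" for i in range(5)]
        tss5 = _tss(genes, [5_000, 7_000, 9_000, 11_000, 13_000])
        base = median_profile(genes[:3], tracks, tss5, flank=500)
        # genes 3/4 sit on signal regions that differ; adding a +X and -X
        # outlier pair around the median leaves the per-bin median unchanged
        for key in tracks:
            tracks[key].values[105:115] = 50.0   # g3 window (center bin 110)
            tracks[key].values[125:135] = -50.0  # g4 window (center bin 130)
        spiked = median_profile(genes, tracks, tss5, flank=500)
        assert spiked.to_numpy() == pytest.approx(base.to_numpy())

    def test_matches_bruteforce_fixture(self):
        tracks = self._tracks(seed=9)
        genes = [f"g{i}" for i in range(10)]
        positions = [3_000 + 1_500 * i for i in range(10)]
        tss10 = _tss(genes, positions)
        profile = median_profile(genes, tracks, tss10, flank=500)
        track = tracks[("H3K9ac", "transformed")]
        stacked = np.stack(
            [track.values[p // 100 - 5 : p // 100 + 5] for p in positions]
        )
        assert profile.loc[("H3K9ac", "transformed")].to_numpy() == pytest.approx(
            np.median(stacked, axis=0)
        )

    def test_empty_cluster_errors(self):
        with pytest.raises(ConfigurationError):
            median_profile([], self._tracks(), _tss(["g"], [10_000]))
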