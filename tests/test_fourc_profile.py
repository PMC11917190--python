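"""Profile processing: loading, normalization, smoothing, binning, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cre4c.fourc_profile import (
    BinnedCounts,
    ViewpointProfile,
    bin_counts,
    load_counts,
    normalize,
    replicate_correlation,
    smooth,
)
from cre4c.io import write_bedgraph

from .conftest import make_toy_map


def _toy_fmap(n_valid_at_least: int = 60):
    """Regular toy map with viewpoint at 0 so no fragment is excluded."""
    _, fmap = make_toy_map(n_units=n_valid_at_least // 2 + 3, viewpoint=0)
    return fmap


def _profile(fmap, values, normalized: bool = False) -> ViewpointProfile:
    values = np.asarray(values, dtype=float)
    assert len(values) == len(fmap.valid_indices())
    return ViewpointProfile(
        fmap, "rep1", values, normalized=values.copy() if normalized else None
    )


def _padded(fmap, head):
    """Vector of the map's valid length starting with ``head``, zero-padded."""
    m = len(fmap.valid_indices())
    out = np.zeros(m)
    out[: len(head)] = head
    return out


class TestLoadCounts:
    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        _, fmap = make_toy_map()
        with pytest.raises(ValueError, match="empty"):
            load_counts(path, fmap)

    def test_malformed_record_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t10\t5\nchr1\tfoo\t20\t1\n")
        _, fmap = make_toy_map()
        with pytest.raises(ValueError, match="line 2"):
            load_counts(path, fmap)

    def test_record_in_blind_fragment_dropped_and_logged(self, tmp_path):
        _, fmap = make_toy_map(n_units=20)
        blind = next(f for f in fmap if not f.valid)  # the edge fragment
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [blind.start], "end": [blind.end], "value": [9]}
        )
        path = tmp_path / "one.bedgraph"
        write_bedgraph(df, path)
        profile = load_counts(path, fmap)
        assert profile.raw.sum() == 0
        assert profile.dropped_records == 1

    def test_bed_positions_counted_per_fragment(self, tmp_path):
        _, fmap = make_toy_map(n_units=20)
        frag = fmap.valid_fragments()[3]
        path = tmp_path / "reads.bed"
        rows = [f"chr1\t{frag.start + o}\t{frag.start + o + 30}\tr\t0\t+" for o in (1, 2, 3)]
        path.write_text("\n".join(rows) + "\n")
        profile = load_counts(path, fmap)
        assert profile.raw[3] == 3
        assert profile.raw.sum() == 3


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,target,expected",
        [([2, 2], 1e6, [5e5, 5e5]), ([1, 3], 100, [25, 75])],
    )
    def test_examples(self, raw, target, expected):
        fmap = _toy_fmap(10)
        prof = normalize(_profile(fmap, _padded(fmap, raw)), target)
        assert np.allclose(prof.normalized[: len(raw)], expected)
        assert np.isclose(prof.normalized.sum(), target)

    def test_all_zero_errors(self):
        fmap = _toy_fmap(10)
        with pytest.raises(ValueError, match="all-zero"):
            normalize(_profile(fmap, _padded(fmap, [0, 0])))

    @settings(max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4), min_size=3, max_size=12).filter(lambda v: sum(v) > 1e-6),
        st.floats(0.01, 100),
    )
    def test_scaling_invariance(self, raw, k):
        fmap = _toy_fmap(16)
        a = normalize(_profile(fmap, _padded(fmap, raw))).normalized
        b = normalize(_profile(fmap, _padded(fmap, [k * v for v in raw]))).normalized
        assert np.allclose(a, b, rtol=1e-9)


class TestSmooth:
    def test_constant_profile_unchanged(self):
        fmap = _toy_fmap(80)
        m = len(fmap.valid_indices())
        prof = smooth(normalize(_profile(fmap, np.full(m, 7.0))), window=30)
        assert np.allclose(prof.smoothed, prof.normalized[0])

    def test_single_spike_spreads_to_height_over_window(self):
        fmap = _toy_fmap(120)
        m = len(fmap.valid_indices())
        raw = np.zeros(m)
        raw[m // 2] = 90.0
        sm = smooth(_profile(fmap, raw, normalized=True), window=30).smoothed
        assert np.isclose(sm.max(), 90.0 / 30)

    def test_interior_matches_direct_convolution(self):
        fmap = _toy_fmap(100)
        m = len(fmap.valid_indices())
        values = np.random.default_rng(0).poisson(20, size=m).astype(float)
        sm = smooth(_profile(fmap, values, normalized=True), window=30).smoothed
        conv = np.convolve(values, np.ones(30) / 30, mode="valid")
        # centered window: 15 left + self + 14 right -> conv index i - 15
        for i in range(15, m - 14):
            assert np.isclose(sm[i], conv[i - 15])

    def test_translation_equivariance(self):
        fmap = _toy_fmap(100)
        m = len(fmap.valid_indices())
        raw = np.zeros(m)
        raw[40] = 60.0
        a = smooth(_profile(fmap, raw, normalized=True), 30).smoothed
        b = smooth(_profile(fmap, np.roll(raw, 7), normalized=True), 30).smoothed
        assert np.allclose(a[20:60], b[27:67])

    def test_too_few_fragments_errors(self):
        fmap = _toy_fmap(10)
        m = len(fmap.valid_indices())
        with pytest.raises(ValueError, match="fewer than window"):
            smooth(_profile(fmap, np.ones(m), normalized=True), window=m + 1)


class TestBinCounts:
    def test_window_has_400_bins(self, background_bundle):
        *_, profiles, _ = background_bundle
        binned = bin_counts(normalize(profiles[0]))
        assert len(binned.values) == 400
        assert binned.edges[0] == profiles[0].fmap.viewpoint - 1_000_000

    def test_span_not_multiple_of_bin_errors(self, background_bundle):
        *_, profiles, _ = background_bundle
        with pytest.raises(ValueError, match="multiple"):
            bin_counts(normalize(profiles[0]), bin_size=3_000)

    def test_single_end_lands_in_first_right_bin(self):
        _, fmap = make_toy_map(n_units=200, viewpoint=10_000)
        iv = fmap.valid_intervals()
        mids = (iv[:, 0] + iv[:, 1]) // 2
        raw = np.zeros(len(iv))
        target = int(np.argmin(np.abs(mids - 12_500)))  # ~viewpoint + 2.5 kb
        raw[target] = 7.0
        binned = bin_counts(_profile(fmap, raw, normalized=True), bin_size=5_000, span=20_000)
        idx = (mids[target] - binned.edges[0]) // 5_000
        assert binned.values[idx] == 7.0
        assert binned.values.sum() == 7.0

    def test_conservation_within_window(self, background_bundle):
        *_, profiles, _ = background_bundle
        prof = normalize(profiles[0])
        binned = bin_counts(prof)
        iv = prof.fmap.valid_intervals()
        mids = (iv[:, 0] + iv[:, 1]) // 2
        inside = (mids >= binned.edges[0]) & (mids < binned.edges[-1])
        assert np.isclose(binned.values.sum(), prof.normalized[inside].sum())


class TestReplicateCorrelation:
    def _binned(self, values):
        edges = np.arange(len(values) + 1) * 5_000
        return BinnedCounts(
            edges=edges, values=np.asarray(values, float), viewpoint=0, bin_size=5_000
        )

    def test_identical_vectors(self):
        a = self._binned([1, 2, 3, 4])
        assert replicate_correlation(a, a).r == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        a = self._binned([1, 2, 3, 4])
        b = self._binned([4, 3, 2, 1])
        assert replicate_correlation(a, b).r == pytest.approx(-1.0)

    def test_zero_variance_reported_as_nan(self):
        result = replicate_correlation(self._binned([1, 1, 1]), self._binned([1, 2, 3]))
        assert np.isnan(result.r) and result.n == 3

    def test_mismatched_binning_errors(self):
        with pytest.raises(ValueError):
            replicate_correlation(self._binned([1, 2, 3]), self._binned([1, 2, 3, 4]))
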