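"""In-silico digestion: site finding, fragment tiling, validity filters."""

import numpy as np
import pytest

from cre4c.restriction_map import (
    CHROM_EDGE,
    ENZYMES,
    Fragment,
    FragmentMap,
    digest,
    filter_fragments,
    find_sites,
)


def brute_force_sites(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


class TestFindSites:
    @pytest.mark.parametrize(
        "seq,enzyme,expected",
        [
            ("AAAA", "NlaIII", []),
            ("CATGCATG", "NlaIII", [0, 4]),
            ("GATCATG", "DpnII", [0]),
            ("GATCATG", "NlaIII", [3]),
            ("NATGCATN", "NlaIII", []),  # N never matches
        ],
    )
    def test_examples(self, seq, enzyme, expected):
        assert [s.pos for s in find_sites(seq, enzyme)] == expected

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            find_sites("CATG", "EcoRI")

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            for enzyme, (motif, _) in ENZYMES.items():
                assert [s.pos for s in find_sites(seq, enzyme)] == brute_force_sites(seq, motif)


class TestDigest:
    def test_toy_genome_cut_convention(self):
        # NlaIII sites at 2 and 18 (cut at motif end), DpnII site at 10 (cut at start)
        fmap = digest("TTCATGTTTTGATCTTTTCATGTT")
        bounds = [(f.start, f.end) for f in fmap]
        assert bounds == [(0, 6), (6, 10), (10, 22), (22, 24)]
        labels = [(f.left_enzyme, f.right_enzyme) for f in fmap]
        assert labels == [
            (CHROM_EDGE, "NlaIII"),
            ("NlaIII", "DpnII"),
            ("DpnII", "NlaIII"),
            ("NlaIII", CHROM_EDGE),
        ]
        # the two middle, differently flanked fragments are valid candidates
        filtered = filter_fragments(fmap, viewpoint=0, min_len=1, exclusion=0)
        assert [f.valid for f in filtered] == [False, True, True, False]

    def test_site_free_genome_single_edge_fragment(self):
        fmap = digest("TTTTTTTTTT")
        assert len(fmap) == 1
        frag = fmap.fragments[0]
        assert frag.left_enzyme == frag.right_enzyme == CHROM_EDGE
        assert not filter_fragments(fmap, 5).fragments[0].valid

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError):
            digest("")

    def test_fragments_tile_genome_and_labels_match_sites(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            fmap = digest(seq)
            # gap-free tiling of [0, L)
            assert fmap.fragments[0].start == 0
            assert fmap.fragments[-1].end == len(seq)
            for a, b in zip(fmap.fragments[:-1], fmap.fragments[1:]):
                assert a.end == b.start
            # flanking labels match the motif at each internal boundary
            for a, b in zip(fmap.fragments[:-1], fmap.fragments[1:]):
                cut = a.end
                assert a.right_enzyme in ENZYMES and b.left_enzyme in ENZYMES
                if a.right_enzyme == "NlaIII":
                    assert seq[cut - 4 : cut] == "CATG"
                if b.left_enzyme == "DpnII":
                    assert seq[cut : cut + 4] == "GATC"

    def test_digest_deterministic(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=2000))
        a, b = digest(seq), digest(seq)
        assert [(f.start, f.end, f.left_enzyme) for f in a] == [
            (f.start, f.end, f.left_enzyme) for f in b
        ]


def _map_from_fragments(frags):
    return FragmentMap(chrom="chr1", fragments=frags)


class TestFilterFragments:
    def test_min_length_boundary(self):
        frags = [
            Fragment("chr1", 0, 39, "NlaIII", "DpnII"),
            Fragment("chr1", 39, 79, "DpnII", "NlaIII"),
        ]
        filtered = filter_fragments(_map_from_fragments(frags), viewpoint=100_000)
        assert [f.valid for f in filtered] == [False, True]  # "smaller than 40 bp"

    def test_viewpoint_exclusion_boundaries(self):
        vp = 10_000
        frags = [
            Fragment("chr1", vp + 4_900, vp + 5_000, "NlaIII", "DpnII"),  # inside zone
            Fragment("chr1", vp + 5_000, vp + 5_100, "DpnII", "NlaIII"),  # abuts boundary
            Fragment("chr1", vp - 5_100, vp - 5_000, "DpnII", "NlaIII"),  # abuts on the left
        ]
        filtered = filter_fragments(_map_from_fragments(frags), viewpoint=vp)
        assert [f.valid for f in filtered] == [False, True, True]

    def test_all_blind_map_has_zero_valid(self):
        frags = [
            Fragment("chr1", i * 100, (i + 1) * 100, "NlaIII", "NlaIII") for i in range(5)
        ]
        filtered = filter_fragments(_map_from_fragments(frags), viewpoint=10_000)
        assert len(filtered.valid_indices()) == 0

    def test_negative_parameters_error(self):
        fmap = _map_from_fragments([Fragment("chr1", 0, 100, "NlaIII", "DpnII")])
        with pytest.raises(ValueError):
            filter_fragments(fmap, 50, min_len=-1)
        with pytest.raises(ValueError):
            filter_fragments(fmap, 50, exclusion=-5)

    def test_valid_count_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=20_000))
            vp = int(rng.integers(2_000, 18_000))
            fmap = filter_fragments(digest(seq), vp, min_len=40, exclusion=1_000)

            # independent oracle: scan sites, form intervals, apply the filters
            cuts = sorted(
                {0, len(seq)}
                | {p + 4 for p in brute_force_sites(seq, "CATG")}
                | {p for p in brute_force_sites(seq, "GATC") if 0 < p < len(seq)}
            )
            n_valid = 0
            for s, e in zip(cuts[:-1], cuts[1:]):
                left_nla = seq[s - 4 : s] == "CATG"
                left_dpn = seq[s : s + 4] == "GATC"
                right_nla = seq[e - 4 : e] == "CATG"
                right_dpn = seq[e : e + 4] == "GATC"
                # at a coincident cut the GATC motif (starting at the cut) flanks
                # the right-hand fragment, the CATG motif (ending there) the left
                left = "D" if left_dpn else ("N" if left_nla else "edge")
                right = "N" if right_nla else ("D" if right_dpn else "edge")
                blind = left == right or "edge" in (left, right)
                short = (e - s) < 40
                near = s < vp + 1_000 and e > vp - 1_000
                if not (blind or short or near):
                    n_valid += 1
            assert len(fmap.valid_indices()) == n_valid

    def test_bed_round_trip(self, tmp_path):
        seq = "".join(np.random.default_rng(4).choice(list("ACGT"), size=5_000))
        fmap = filter_fragments(digest(seq), 2_500)
        path = tmp_path / "map.bed"
        fmap.to_bed(path)
        loaded = FragmentMap.from_bed(path, viewpoint=2_500)
        assert [(f.start, f.end, f.left_enzyme, f.right_enzyme, f.valid) for f in loaded] == [
            (f.start, f.end, f.left_enzyme, f.right_enzyme, f.valid) for f in fmap
        ]
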