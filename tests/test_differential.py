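"""Shared/gained/lost classification, distance classes, densities, annotation."""

import numpy as np
import pandas as pd
import pytest

from cre4c._intervals import merge_overlapping
from cre4c.differential import (
    annotate_promoter,
    classify,
    distance_class,
    distance_density,
)


def _random_disjoint(rng, n, span=1_000_000, max_len=5_000):
    starts = np.sort(rng.choice(span, size=n, replace=False))
    out = []
    last = -1
    for s in starts:
        s = max(int(s), last + 1)
        e = s + int(rng.integers(100, max_len))
        out.append((s, e))
        last = e
    return out


def brute_force_class_counts(exp, bases, min_overlap=1):
    """Independent pairwise-overlap oracle for the class partition."""
    def olap(a, b):
        return min(a[1], b[1]) - max(a[0], b[0]) >= min_overlap

    all_base = [iv for b in bases for iv in b]
    shared = sum(1 for q in exp if any(olap(q, r) for r in all_base))
    gained = len(exp) - shared
    merged = [tuple(iv) for iv in merge_overlapping(all_base)] if all_base else []
    lost = sum(1 for r in merged if not any(olap(r, q) for q in exp))
    return shared, gained, lost, len(exp) + lost


class TestClassify:
    def test_toy_example(self):
        # baseline [150,250) overlaps expressing [100,200): it is "present in
        # both" and hence accounted for by the shared region, not lost
        result = classify(
            [(100, 200), (500, 600)], [[(150, 250)], [(800, 900)]]
        )
        assert result.counts == {"shared": 1, "gained": 1, "lost": 1}
        assert sum(result.counts.values()) == 3  # distinct regions across lines

    def test_identical_sets_all_shared(self):
        regions = [(0, 100), (500, 700)]
        result = classify(regions, [regions, regions])
        assert result.counts == {"shared": 2, "gained": 0, "lost": 0}

    def test_disjoint_sets(self):
        result = classify([(0, 100)], [[(200, 300)], [(250, 400)]])
        # the two overlapping baseline regions merge into one lost region
        assert result.counts == {"shared": 0, "gained": 1, "lost": 1}

    def test_empty_everything_errors(self):
        with pytest.raises(ValueError):
            classify([], [[], []])

    def test_partition_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            exp = _random_disjoint(rng, int(rng.integers(1, 25)))
            bases = [
                _random_disjoint(rng, int(rng.integers(1, 25))) for _ in range(2)
            ]
            result = classify(exp, bases)
            s, g, l, total = brute_force_class_counts(exp, bases)
            assert result.counts == {"shared": s, "gained": g, "lost": l}
            assert sum(result.counts.values()) == total
            assert len(result.table) == total

    def test_symmetric_under_baseline_reordering(self):
        rng = np.random.default_rng(1)
        exp = _random_disjoint(rng, 15)
        b1 = _random_disjoint(rng, 10)
        b2 = _random_disjoint(rng, 12)
        assert classify(exp, [b1, b2]).counts == classify(exp, [b2, b1]).counts


class TestDistanceClass:
    @pytest.mark.parametrize(
        "midpoint,expected",
        [
            (0, "near"),
            (199_999, "near"),
            (200_000, "medium"),  # boundary assigned to medium
            (500_000, "medium"),  # closed upper boundary
            (500_001, "far"),
            (750_000, "far"),
        ],
    )
    def test_boundaries(self, midpoint, expected):
        region = (midpoint - 50, midpoint + 50)
        assert distance_class(region, viewpoint=0) == expected

    def test_trans_region_errors(self):
        from cre4c.interaction_caller import PCRE

        pcre = PCRE("chr2", 0, 100, [], 0.0)
        with pytest.raises(ValueError, match="cis"):
            distance_class(pcre, viewpoint=0, chrom="chr6")


class TestDistanceDensity:
    def _classified(self, rows):
        from cre4c.differential import ClassifiedPCREs

        table = pd.DataFrame(rows, columns=["chrom", "start", "end", "pcre_class", "source"])
        return ClassifiedPCREs(table=table, counts={})

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        rows = [
            ("chr1", int(d), int(d) + 1000, "shared", "x")
            for d in rng.uniform(2e5, 8e5, size=30)
        ]
        dens = distance_density(self._classified(rows), viewpoint=0, bandwidth=20_000)
        grid, y = dens["shared"]
        assert abs(np.trapezoid(y, grid) - 1.0) < 1e-3

    def test_mode_at_common_distance(self):
        rows = [("chr1", 399_000, 401_000, "gained", "x")] * 5
        dens = distance_density(self._classified(rows), viewpoint=0, bandwidth=10_000)
        grid, y = dens["gained"]
        assert abs(grid[np.argmax(y)] - 400_000) < 1_000

    def test_matches_brute_force_kernel_sum(self):
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        rows = [
            ("chr1", int(x) - 500, int(x) + 500, "lost", "x")
            for x in rng.uniform(1e5, 9e5, size=20)
        ]
        d = np.array([(s + e) / 2 for _, s, e, _, _ in rows])
        bw = 30_000.0
        grid = np.linspace(0, 1e6, 200)
        dens = distance_density(self._classified(rows), viewpoint=0, bandwidth=bw, grid=grid)
        _, y = dens["lost"]
        expected = np.array([np.mean(norm.pdf(g, loc=d, scale=bw)) for g in grid])
        assert np.allclose(y, expected, atol=1e-12)

    def test_single_pcre_class_omitted_with_warning(self):
        rows = [("chr1", 0, 1000, "gained", "x")]
        with pytest.warns(UserWarning, match="gained"):
            dens = distance_density(self._classified(rows), viewpoint=0)
        assert "gained" not in dens


class TestAnnotatePromoter:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [10_000, 50_000, 90_000],
            "end": [20_000, 60_000, 95_000],
            "name": ["geneA", "geneB", "geneC"],
            "strand": ["+", "-", "+"],
        }
    )

    def test_upstream_of_plus_strand_tss_is_promoter(self):
        assert annotate_promoter([(9_400, 9_600)], self.GENES) == ["promoter"]

    def test_upstream_of_minus_strand_tss_is_promoter(self):
        # for geneB the TSS is at end=60,000; upstream extends to the right
        assert annotate_promoter([(60_500, 60_700)], self.GENES) == ["promoter"]

    def test_gene_body_is_exonic_and_distal_is_noncoding(self):
        labels = annotate_promoter([(15_000, 15_500), (70_000, 70_100)], self.GENES)
        assert labels == ["exonic", "non-coding"]

    def test_missing_strand_errors(self):
        genes = self.GENES.drop(columns=["strand"])
        with pytest.raises(ValueError, match="strand"):
            annotate_promoter([(0, 10)], genes)

    def test_matches_brute_force_interval_logic(self):
        rng = np.random.default_rng(4)
        pcres = _random_disjoint(rng, 30, span=100_000, max_len=2_000)
        labels = annotate_promoter(pcres, self.GENES, upstream=1000, downstream=100)
        for (s, e), label in zip(pcres, labels):
            proms = []
            for g in self.GENES.itertuples():
                tss = g.start if g.strand == "+" else g.end
                proms.append(
                    (tss - 1000, tss + 100) if g.strand == "+" else (tss - 100, tss + 1000)
                )
            in_prom = any(s < pe and e > ps for ps, pe in proms)
            in_gene = any(s < g.end and e > g.start for g in self.GENES.itertuples())
            expected = "promoter" if in_prom else ("exonic" if in_gene else "non-coding")
            assert label == expected
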