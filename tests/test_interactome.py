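"""Promoters, enhancers, interaction filters and the merged map."""

import numpy as np
import pandas as pd
import pytest

from cisrec.interactome import (AnchorFilter, ChromatinInteraction, Gene,
                                GenomicInterval, define_promoters,
                                enhancers_from_ernas, filter_interactions,
                                map_variant_targets, merge_interactomes,
                                restrict_to_celltype)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestPromoters:
    def test_plus_strand_window(self):
        g = Gene("g", "chr1", 10000, 12000, "+")
        p = define_promoters([g])["g"]
        assert (p.start, p.end) == (8000, 10500)

    def test_minus_strand_window(self):
        g = Gene("g", "chr1", 8000, 10001, "-")  # TSS at 10000
        p = define_promoters([g])["g"]
        assert (p.start, p.end) == (9500, 12000)

    def test_clipped_at_origin(self):
        g = Gene("g", "chr1", 100, 1300, "+")
        p = define_promoters([g])["g"]
        assert (p.start, p.end) == (0, 600)

    def test_missing_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            Gene("g", "chr1", 0, 10, ".")


class TestEnhancers:
    @pytest.mark.parametrize("erna,expected", [
        ((1000, 1400), (1100, 1300)),
        ((1000, 1002), (901, 1101)),
        ((50, 52), (0, 151)),
    ])
    def test_center_flanks(self, erna, expected):
        e = enhancers_from_ernas([iv(*erna)])[0]
        assert (e.start, e.end) == expected


def _chia(a, b, pet):
    return ChromatinInteraction(a, b, "ChIA-PET", pet)


class TestFilters:
    def test_pet_threshold_boundary(self):
        keep = _chia(iv(0, 100), iv(500, 600), 3)
        drop = _chia(iv(0, 100), iv(500, 600), 2)
        out = filter_interactions([keep, drop], min_pet=3)
        assert out == [keep]

    def test_non_chiapet_untouched_by_pet(self):
        im = ChromatinInteraction(iv(0, 100), iv(500, 600), "IM-PET", 0.1)
        assert filter_interactions([im], min_pet=3) == [im]

    def test_min_pet_one_is_identity(self):
        ias = [_chia(iv(0, 100), iv(500, 600), p) for p in (1, 2, 5)]
        assert filter_interactions(ias, min_pet=1) == ias

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ChromatinInteraction(iv(0, 1), iv(2, 3), "Hi-C", 5)

    def test_anchor_filter_requires_overlap(self):
        track = [iv(250, 400)]
        hit = ChromatinInteraction(iv(100, 300), iv(5000, 5100), "IM-PET", 1)
        miss = ChromatinInteraction(iv(400, 500), iv(5000, 5100), "IM-PET", 1)
        out = filter_interactions([hit, miss], anchor_filters=[
            AnchorFilter(track, mode="any")])
        assert out == [hit]


class TestCellTypeRestriction:
    def test_overlap_retained_touching_removed(self):
        dhs = [iv(250, 400)]
        keep = ChromatinInteraction(iv(100, 300), iv(900, 1000), "DHS-corr", 0.9)
        drop = ChromatinInteraction(iv(100, 250), iv(900, 1000), "CAGE-corr", 0.9)
        out = restrict_to_celltype([keep, drop], dhs)
        assert out == [keep]

    def test_chiapet_passes_through(self):
        ia = _chia(iv(100, 300), iv(900, 1000), 5)
        assert restrict_to_celltype([ia], [iv(5000, 5100)]) == [ia]

    def test_empty_dhs_empties_universal_sources(self):
        ia = ChromatinInteraction(iv(100, 300), iv(900, 1000), "DHS-corr", 0.9)
        assert restrict_to_celltype([ia], []) == []


@pytest.fixture
def two_genes():
    return [Gene("g1", "chr1", 10000, 12000, "+"),
            Gene("g2", "chr1", 10300, 12300, "+")]


class TestMerge:
    def test_multi_gene_anchor_assigned_to_all(self, two_genes):
        promoters = define_promoters(two_genes)  # overlap around 10000-10500
        ia = _chia(iv(50000, 50200), iv(10000, 10100), 5)
        m = merge_interactomes([ia], promoters)
        for g in ("g1", "g2"):
            enh = [r.interval for r in m.intervals(g) if r.role == "enhancer"]
            assert iv(50000, 50200) in enh

    def test_promoter_promoter_dropped(self, two_genes):
        g3 = Gene("g3", "chr1", 90000, 92000, "+")
        promoters = define_promoters(two_genes + [g3])
        pp = _chia(iv(10000, 10100), iv(88200, 88300), 5)
        m = merge_interactomes([pp], promoters)
        assert m.n_enhancers() == 0

    def test_gene_without_interactions_keeps_promoter(self, two_genes):
        promoters = define_promoters(two_genes)
        m = merge_interactomes([], promoters)
        for g in ("g1", "g2"):
            regions = m.intervals(g)
            assert len(regions) == 1 and regions[0].role == "promoter"

    def test_merge_idempotent_under_duplication(self, two_genes):
        promoters = define_promoters(two_genes)
        ias = [_chia(iv(50000, 50200), iv(10000, 10100), 5),
               _chia(iv(60000, 60200), iv(10400, 10600), 4)]
        assert merge_interactomes(ias, promoters) == \
            merge_interactomes(ias + ias, promoters)

    def test_every_enhancer_traces_to_an_interaction(self, small_cohort):
        anchors = set()
        for ia in small_cohort.interactions:
            for a in (ia.anchor1, ia.anchor2):
                anchors.add((a.chrom, a.start, a.end))
        for g in small_cohort.ep_map.genes():
            for r in small_cohort.ep_map.intervals(g):
                if r.role == "enhancer":
                    key = (r.interval.chrom, r.interval.start, r.interval.end)
                    assert key in anchors


class TestVariantTargets:
    @pytest.fixture
    def simple_map(self, two_genes):
        promoters = define_promoters(two_genes[:1])
        ias = [_chia(iv(50000 + i * 1000, 50200 + i * 1000),
                     iv(10000, 10100), 5) for i in range(4)]
        return merge_interactomes(ias, promoters)

    def test_four_samples_four_enhancers_give_four_triples(self, simple_map):
        v = pd.DataFrame({
            "sample": [f"s{i}" for i in range(4)],
            "chrom": "chr1",
            "pos": [50100 + i * 1000 for i in range(4)],
            "call": "loss",
        })
        out = map_variant_targets(v, simple_map)
        assert len(out) == 4 and set(out["gene_id"]) == {"g1"}
        assert out["sample"].nunique() == 4

    def test_none_call_not_assigned(self, simple_map):
        v = pd.DataFrame({"sample": ["s0"], "chrom": "chr1",
                          "pos": [50100], "call": "none"})
        assert len(map_variant_targets(v, simple_map)) == 0

    def test_end_coordinate_excluded_half_open(self, simple_map):
        v = pd.DataFrame({"sample": ["s0"], "chrom": "chr1",
                          "pos": [50200], "call": "gain"})
        assert len(map_variant_targets(v, simple_map)) == 0

    def test_unknown_chrom_skipped(self, simple_map):
        v = pd.DataFrame({"sample": ["s0"], "chrom": "chrZ",
                          "pos": [50100], "call": "gain"})
        assert len(map_variant_targets(v, simple_map)) == 0
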