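"""Generator determinism, validation, planted structure and round-trips."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

import cisrec
from cisrec import io as cio
from cisrec.synthetic_data import (FILES, SyntheticCohortConfig,
                                   generate_annotation, generate_cohort,
                                   read_cohort, write_cohort)


def _tiny_cfg(**kw):
    base = dict(n_samples=10, n_genes=40, genome_length=300_000,
                variants_per_sample_mean=30, n_planted_tds=2,
                planted_recurrence=4, n_planted_cds=2, seed=11)
    base.update(kw)
    return SyntheticCohortConfig(**base)


def _dir_digests(d):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(d).iterdir())}


class TestValidation:
    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            _tiny_cfg(n_genes=0).validate()

    def test_recurrence_above_cohort_rejected(self):
        with pytest.raises(ValueError, match="planted_recurrence"):
            _tiny_cfg(planted_recurrence=11).validate()

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="genome too small"):
            _tiny_cfg(genome_length=50_000).validate()


class TestAnnotation:
    def test_genes_non_overlapping_and_reproducible(self):
        cfg = _tiny_cfg()
        a1 = generate_annotation(cfg)
        a2 = generate_annotation(cfg)
        assert [g.start for g in a1.genes] == [g.start for g in a2.genes]
        spans = sorted((g.start, g.end) for g in a1.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_seed_changes_coordinates(self):
        a1 = generate_annotation(_tiny_cfg(seed=1))
        a2 = generate_annotation(_tiny_cfg(seed=2))
        assert [g.tss for g in a1.genes] != [g.tss for g in a2.genes]

    def test_ernas_clear_of_promoters(self):
        from cisrec.interactome import define_promoters, enhancers_from_ernas

        a = generate_annotation(_tiny_cfg())
        promoters = define_promoters(a.genes)
        for e in enhancers_from_ernas(a.ernas):
            assert not any(e.overlaps(p) for p in promoters.values())


class TestInteractome:
    def test_planted_td_linked_to_own_promoter(self, small_cohort):
        from cisrec.interactome import define_promoters

        promoters = define_promoters(small_cohort.annotation.genes)
        for td in small_cohort.truth["planted_tds"]:
            prom = promoters[td["gene"]]
            linked = [ia for ia in small_cohort.interactions
                      if ia.anchor2.overlaps(prom) or ia.anchor1.overlaps(prom)]
            assert linked, td["gene"]

    def test_low_pet_fraction_binomial(self):
        cfg = _tiny_cfg(fraction_low_pet=0.2, interactions_per_source=200)
        co = generate_cohort(cfg)
        bg_chia = [ia for ia in co.interactions if ia.source == "ChIA-PET"]
        n_planted = sum(len(t["sites"]) > 0 for t in co.truth["planted_tds"])
        low = sum(1 for ia in bg_chia if ia.support < 3)
        n_bg = 200
        sd = np.sqrt(n_bg * 0.2 * 0.8)
        assert abs(low - 0.2 * n_bg) < 4 * sd

    def test_zero_promoter_promoter_fraction(self):
        from cisrec.interactome import define_promoters

        cfg = _tiny_cfg(promoter_promoter_fraction=0.0)
        co = generate_cohort(cfg)
        promoters = list(define_promoters(co.annotation.genes).values())

        def in_prom(a):
            return any(a.overlaps(p) for p in promoters)

        both = [ia for ia in co.interactions
                if in_prom(ia.anchor1) and in_prom(ia.anchor2)]
        assert both == []


class TestVariants:
    def test_planted_recurrence_by_construction(self, small_cohort,
                                                small_recurrence):
        for td in small_cohort.truth["planted_tds"]:
            assert small_recurrence.loc[td["gene"], "M"] >= td["recurrence"]

    def test_exclusivity_pairs_disjoint(self, small_cohort):
        coding = small_cohort.coding_variants
        for cd_gene, td_gene in small_cohort.truth["exclusivity_pairs"]:
            cd_samples = set(coding.loc[coding["gene"] == cd_gene, "sample"])
            td = next(t for t in small_cohort.truth["planted_tds"]
                      if t["gene"] == td_gene)
            assert cd_samples.isdisjoint(td["samples"])

    def test_per_sample_mean_within_three_se(self):
        cfg = _tiny_cfg(n_samples=50, variants_per_sample_mean=100.0,
                        genome_length=400_000, n_genes=50)
        co = generate_cohort(cfg)
        counts = co.variants.groupby("sample").size()
        se = np.sqrt(100.0 / 50)  # Poisson sd / sqrt(n)
        assert abs(counts.mean() - 100.0) < 3 * se

    def test_variant_ref_matches_genome(self, small_cohort):
        genome = small_cohort.genome[small_cohort.config.chrom]
        sub = small_cohort.variants.iloc[::29]
        for row in sub.itertuples():
            assert genome[row.pos] == row.ref
            assert row.alt != row.ref


class TestSerialization:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = _tiny_cfg()
        write_cohort(generate_cohort(cfg), tmp_path / "a")
        write_cohort(generate_cohort(cfg), tmp_path / "b")
        assert _dir_digests(tmp_path / "a") == _dir_digests(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        write_cohort(generate_cohort(_tiny_cfg(seed=1)), tmp_path / "a")
        write_cohort(generate_cohort(_tiny_cfg(seed=2)), tmp_path / "b")
        assert _dir_digests(tmp_path / "a") != _dir_digests(tmp_path / "b")

    def test_round_trip_through_readers(self, tmp_path):
        co = generate_cohort(_tiny_cfg())
        write_cohort(co, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert back.variants.equals(co.variants)
        assert back.coding_variants.equals(co.coding_variants)
        assert len(back.interactions) == len(co.interactions)
        assert back.genome == co.genome
        assert back.truth["planted_tds"] == co.truth["planted_tds"]
        assert back.ep_map == co.ep_map
        canon = lambda g: {tuple(sorted(e)) for e in g.edges}
        assert canon(back.ppi) == canon(co.ppi)

    def test_meme_round_trip(self, tmp_path):
        co = generate_cohort(_tiny_cfg())
        cio.write_meme(co.pwms, tmp_path / "m.meme")
        back = cio.read_meme(tmp_path / "m.meme")
        assert [p.motif_id for p in back] == [p.motif_id for p in co.pwms]
        for a, b in zip(back, co.pwms):
            assert np.allclose(a.matrix, b.matrix, atol=2e-3)
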