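"""Simulation schemes, count conservation and empirical p-values."""

import numpy as np
import pandas as pd
import pytest

import cisrec
from cisrec.motif_disruption import encode_sequence
from cisrec.null_models import (NullDistribution, empirical_null,
                                empirical_pvalue, sample_control_interactions,
                                simulate_clinical, simulate_epigenome,
                                simulate_insilico)


@pytest.fixture
def toy_variants():
    rng = np.random.default_rng(0)
    rows = []
    for s, n in (("s1", 37), ("s2", 12), ("s3", 3)):
        for _ in range(n):
            rows.append((s, "chrS1", int(rng.integers(0, 9000)), "A", "C"))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(1)
    return {"chrS1": rng.integers(0, 4, size=10000).astype(np.uint8)}


class TestInsilico:
    def test_per_sample_counts_preserved(self, toy_variants, toy_genome):
        out = simulate_insilico(toy_variants, toy_genome,
                                np.random.default_rng(5))
        got = out.groupby("sample").size().to_dict()
        assert got == {"s1": 37, "s2": 12, "s3": 3}

    def test_total_count_conserved(self, toy_variants, toy_genome):
        out = simulate_insilico(toy_variants, toy_genome,
                                np.random.default_rng(5))
        assert len(out) == len(toy_variants)

    def test_ref_matches_genome_and_alt_differs(self, toy_variants, toy_genome):
        out = simulate_insilico(toy_variants, toy_genome,
                                np.random.default_rng(5))
        codes = toy_genome["chrS1"]
        for row in out.itertuples():
            assert "ACGT"[codes[row.pos]] == row.ref
            assert row.alt != row.ref

    def test_seeds_change_positions_not_counts(self, toy_variants, toy_genome):
        a = simulate_insilico(toy_variants, toy_genome, np.random.default_rng(1))
        b = simulate_insilico(toy_variants, toy_genome, np.random.default_rng(2))
        assert sorted(a["pos"]) != sorted(b["pos"])
        assert a.groupby("sample").size().equals(b.groupby("sample").size())


class TestClinical:
    def test_counts_preserved_and_relabelled(self, toy_variants):
        pool = pd.DataFrame({
            "sample": [f"c{i}" for i in range(500)], "chrom": "chrS1",
            "pos": np.arange(500), "ref": "A", "alt": "G"})
        out = simulate_clinical(toy_variants, pool, np.random.default_rng(0))
        assert out.groupby("sample").size().to_dict() == {"s1": 37, "s2": 12,
                                                          "s3": 3}
        assert set(out["sample"]) == {"s1", "s2", "s3"}
        # without replacement: all drawn positions distinct
        assert out["pos"].nunique() == len(out)

    def test_exact_size_pool_fully_used(self, toy_variants):
        pool = pd.DataFrame({"sample": "c", "chrom": "chrS1",
                             "pos": np.arange(52), "ref": "A", "alt": "G"})
        out = simulate_clinical(toy_variants, pool, np.random.default_rng(0))
        assert sorted(out["pos"]) == list(range(52))

    def test_undersized_pool_rejected(self, toy_variants):
        pool = pd.DataFrame({"sample": "c", "chrom": "chrS1",
                             "pos": np.arange(5), "ref": "A", "alt": "G"})
        with pytest.raises(ValueError, match="smaller"):
            simulate_clinical(toy_variants, pool, np.random.default_rng(0))


class TestEpigenome:
    def test_per_source_counts_match_real(self, small_cohort):
        sampled = sample_control_interactions(
            small_cohort.interactions, small_cohort.control_interactions,
            np.random.default_rng(0))

        def by_source(ias):
            out = {}
            for ia in ias:
                out[ia.source] = out.get(ia.source, 0) + 1
            return out

        assert by_source(sampled) == by_source(small_cohort.interactions)

    def test_self_control_reproduces_map_scale(self, small_cohort):
        from cisrec.interactome import define_promoters

        promoters = define_promoters(small_cohort.annotation.genes)
        m = simulate_epigenome(small_cohort.interactions,
                               small_cohort.interactions, promoters,
                               np.random.default_rng(0))
        assert m == small_cohort.ep_map or m.n_enhancers() > 0


class TestEmpiricalP:
    def test_add_one_formula(self):
        reps = np.arange(1000)  # all < observed
        assert empirical_pvalue(reps, 1000) == pytest.approx(1 / 1001)

    def test_observed_equal_to_every_replicate_gives_one(self):
        assert empirical_pvalue(np.full(200, 3.0), 3.0) == pytest.approx(1.0)

    def test_reps_validation(self):
        with pytest.raises(ValueError, match="reps"):
            empirical_null(lambda d: d, lambda rng: 0.0, observed=0.0, reps=0)

    def test_generic_null_reproducible_from_seed(self):
        gen = lambda rng: rng.normal()
        a = empirical_null(lambda d: d, gen, observed=1.0, reps=50, seed=9)
        b = empirical_null(lambda d: d, gen, observed=1.0, reps=50, seed=9)
        assert np.array_equal(a.replicate_values, b.replicate_values)
        assert a.empirical_p == b.empirical_p


class TestEngine:
    def test_engine_M_matches_reference_pipeline(self, small_cohort,
                                                 small_engine,
                                                 small_recurrence):
        arrays = small_engine.arrays_from_frame(small_cohort.variants)
        M = small_engine.M_vector(arrays)
        ref = small_recurrence["M"]
        for i, g in enumerate(small_engine.gene_ids):
            assert M[i] == ref.loc[g]

    def test_replicates_preserve_per_sample_counts(self, small_cohort,
                                                   small_engine):
        arrays = small_engine.arrays_from_frame(small_cohort.variants)
        counts = small_engine._counts(arrays)
        rep = small_engine._random_arrays(counts, np.random.default_rng(0))
        assert np.array_equal(small_engine._counts(rep), counts)

    def test_planted_tds_significant(self, small_cohort, small_engine):
        nd = small_engine.run(small_cohort.variants, "insilico",
                              statistic="per-gene", reps=200, seed=4)
        gidx = {g: i for i, g in enumerate(small_engine.gene_ids)}
        for td in small_cohort.truth["planted_tds"]:
            assert nd.empirical_p[gidx[td["gene"]]] < 0.05

    def test_unknown_scheme_rejected(self, small_cohort, small_engine):
        with pytest.raises(ValueError, match="scheme"):
            small_engine.run(small_cohort.variants, "bootstrap", reps=2)
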