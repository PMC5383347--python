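import numpy as np
import pytest
from hypothesis import settings

import cisrec
from cisrec.motif_disruption import build_disruption_index, encode_sequence
from cisrec.null_models import RecurrenceNullEngine

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    return cisrec.SyntheticCohortConfig(
        n_samples=20, n_genes=100, genome_length=700_000,
        variants_per_sample_mean=60, n_planted_tds=3, planted_recurrence=5,
        n_planted_cds=3, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return cisrec.generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_genome_codes(small_cohort):
    return {c: encode_sequence(s) for c, s in small_cohort.genome.items()}


@pytest.fixture(scope="session")
def small_index(small_cohort, small_genome_codes):
    return build_disruption_index(small_genome_codes, small_cohort.pwms)


@pytest.fixture(scope="session")
def small_engine(small_cohort, small_index, small_genome_codes):
    return RecurrenceNullEngine(small_index, small_cohort.ep_map,
                                small_cohort.truth["cohort"],
                                small_genome_codes)


@pytest.fixture(scope="session")
def small_recurrence(small_cohort, small_index):
    """Observed recurrence table of the session cohort."""
    variants = small_cohort.variants.copy()
    alt = np.array([encode_sequence(a)[0] for a in variants["alt"]])
    variants["changing"] = small_index.is_changing(
        small_cohort.config.chrom, variants["pos"].to_numpy(), alt)
    assignments = cisrec.map_variant_targets(variants, small_cohort.ep_map)
    return cisrec.compute_recurrence(
        assignments, small_cohort.truth["cohort"],
        genes=[g.gene_id for g in small_cohort.annotation.genes])
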