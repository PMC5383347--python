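"""End-to-end orchestration: simulate/load inputs, call motif changes, build
the enhancer–promoter map, compute recurrence, run simulation nulls, score
networks, evaluate driver modules and variant complementarity.

A single :class:`PipelineConfig` (constructable from YAML) carries every
tunable parameter; defaults reproduce the analysis conditions (motif p
cutoff 1e-5, PET >= 3, recurrence thresholds 2/5, 1,000 replicates).  Every
run writes a provenance record (config hash, master seed, package
versions) and stage outputs in dependency order, and re-running with the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .complementarity import exclusivity_matrix, group_comparison
from .driver_modules import (classify_2020, interaction_enrichment,
                             modular_scores, roc_evaluate)
from .interactome import map_variant_targets, define_promoters
from .motif_disruption import build_disruption_index, call_variants, encode_sequence
from .networks import causal_scores, relative_degree, relative_scores
from .null_models import RecurrenceNullEngine
from .recurrence import compute_recurrence
from .synthetic_data import (SyntheticCohort, SyntheticCohortConfig,
                             build_ep_map, generate_cohort, read_cohort,
                             write_cohort)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "motifs", "build-map", "recur", "null",
              "netscore", "modules", "complement")


@dataclass
class PipelineConfig:
    """Parameters of one full pipeline run."""
    out_dir: str = "cisrec_out"
    cohort_label: str = "synthetic"
    input_dir: Optional[str] = None  # load a serialized cohort instead
    simulate: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    motif_cutoff: float = 1e-5
    min_pet: int = 3
    recurrence_low: int = 2
    recurrence_high: int = 5
    reps: int = 1000
    null_schemes: Tuple[str, ...] = ("insilico", "clinical", "epigenome")
    null_statistic: str = "n-recurrent"
    max_background_pairs: int = 20000
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.motif_cutoff < 1):
            raise ValueError("motif_cutoff must be in (0, 1)")
        if not (0 < self.recurrence_low < self.recurrence_high):
            raise ValueError("need 0 < recurrence_low < recurrence_high")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in self.null_schemes:
            if s not in ("insilico", "clinical", "epigenome"):
                raise ValueError(f"unknown null scheme {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            raw["simulate"] = SyntheticCohortConfig(**raw["simulate"])
        for key in ("null_schemes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    recurrence: Optional[pd.DataFrame] = None
    nulls: Dict[str, dict] = field(default_factory=dict)
    causal: Optional[pd.DataFrame] = None
    degree: Optional[pd.DataFrame] = None
    driver_labels: Optional[pd.DataFrame] = None
    enrichment: Dict[str, dict] = field(default_factory=dict)
    modular: Optional[pd.DataFrame] = None
    roc: Optional[pd.DataFrame] = None
    complementarity: Optional[pd.DataFrame] = None
    complementarity_tests: Optional[pd.DataFrame] = None


def _write_provenance(cfg: PipelineConfig, out: Path) -> None:
    import scipy

    cio.write_json(dict(
        config=cfg.to_dict(),
        config_sha256=cfg.digest(),
        seed=cfg.seed,
        versions=dict(cisrec=__version__, numpy=np.__version__,
                      scipy=scipy.__version__, pandas=pd.__version__),
    ), out / "provenance.json")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the configured stages in dependency order; see module docstring."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_provenance(cfg, out)
    stages = set(cfg.stages)

    # --- inputs
    if cfg.input_dir is not None:
        cohort = read_cohort(cfg.input_dir)
    else:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        cohort = generate_cohort(sim_cfg)
        if "simulate" in stages:
            write_cohort(cohort, out / "inputs")
    result = PipelineResult(cohort)
    genome_codes = {c: encode_sequence(s) for c, s in cohort.genome.items()}
    samples = cohort.truth["cohort"]
    gene_ids = [g.gene_id for g in cohort.annotation.genes]

    # --- motif disruption
    index = build_disruption_index(genome_codes, cohort.pwms,
                                   cutoff=cfg.motif_cutoff)
    variants = cohort.variants.copy()
    changing = np.zeros(len(variants), dtype=bool)
    for chrom, sub in variants.groupby("chrom"):
        alt = np.array([encode_sequence(a)[0] for a in sub["alt"]])
        changing[sub.index] = index.is_changing(chrom, sub["pos"].to_numpy(), alt)
    variants["changing"] = changing
    if "motifs" in stages:
        detail = call_variants(variants[variants["changing"]], genome_codes,
                               cohort.pwms, cutoff=cfg.motif_cutoff)
        detail = detail[detail["call"] != "none"]
        detail_out = detail.copy()
        detail_out["pos"] += 1
        detail_out.to_csv(out / "motif_calls.tsv", sep="\t", index=False)

    # --- enhancer-promoter map
    ep_map = build_ep_map(cohort.config, cohort.annotation,
                          cohort.interactions, min_pet=cfg.min_pet)
    if "build-map" in stages:
        cio.write_ep_map(ep_map, out / "ep_map.tsv")

    # --- recurrence
    assignments = map_variant_targets(variants, ep_map)
    rec = compute_recurrence(assignments, samples, genes=gene_ids,
                             low=cfg.recurrence_low, high=cfg.recurrence_high)
    result.recurrence = rec
    if "recur" in stages:
        rec_out = rec.copy()
        rec_out["samples"] = rec_out["samples"].map(
            lambda s: ",".join(sorted(s)))
        rec_out.to_csv(out / "recurrence.tsv", sep="\t")
    M = rec["M"].to_dict()

    # --- simulation nulls
    if "null" in stages:
        engine = RecurrenceNullEngine(index, ep_map, samples, genome_codes)
        promoters = define_promoters(cohort.annotation.genes)
        for i, scheme in enumerate(cfg.null_schemes):
            nd = engine.run(
                variants, scheme, statistic=cfg.null_statistic,
                reps=cfg.reps, seed=[cfg.seed % (2 ** 31), 100 + i],
                control_pool=cohort.control_pool,
                real_interactions=cohort.interactions,
                control_interactions=cohort.control_interactions,
                promoters=promoters)
            summary = dict(scheme=scheme, statistic=cfg.null_statistic,
                           observed=nd.observed, empirical_p=nd.empirical_p,
                           reps=nd.reps,
                           replicate_mean=float(np.mean(nd.replicate_values)))
            result.nulls[scheme] = summary
            np.savetxt(out / f"null_{scheme}_replicates.txt",
                       nd.replicate_values, fmt="%g")
            cio.write_json(summary, out / f"null_{scheme}.json")

    # --- regulatory network scores
    if "netscore" in stages:
        raw = causal_scores(cohort.regulatory_dag, path_mode="shortest")
        try:
            result.causal = relative_scores(raw).table
            result.causal.to_csv(out / "causal_scores.tsv", sep="\t")
        except ValueError:
            logger.warning("all-zero causal scores; netscore stage skipped")
        groups = {
            "TD-high": set(rec.index[rec["category"] == "high"]),
            "TD-low": set(rec.index[rec["category"] == "low"]),
        }
        labels = classify_2020(cohort.coding_variants)
        cd_set = set(labels.index[labels["driver_class"] != "none"])
        groups["CD"] = cd_set
        result.degree = relative_degree(cohort.ppi, groups)
        result.degree.to_csv(out / "relative_degree.tsv", sep="\t")

    # --- driver modules
    labels = classify_2020(cohort.coding_variants)
    result.driver_labels = labels
    cd_set = set(labels.index[labels["driver_class"] != "none"])
    td_set = set(rec.index[rec["recurrent"]])
    if "modules" in stages:
        labels.to_csv(out / "driver_labels.tsv", sep="\t")
        if cd_set and td_set:
            for i, mode in enumerate(("node", "link")):
                er = interaction_enrichment(
                    cohort.ppi, cd_set, td_set, mode=mode, reps=cfg.reps,
                    seed=[cfg.seed % (2 ** 31), 200 + i])
                result.enrichment[mode] = dict(
                    observed=er.observed, ratio=er.ratio,
                    empirical_p=er.empirical_p, mode=mode, reps=er.reps)
            cio.write_json(result.enrichment, out / "enrichment.json")
        mod = modular_scores(cohort.ppi, M)
        result.modular = mod
        mod.to_csv(out / "modular_scores.tsv", sep="\t")
        if cd_set and len(cd_set) < len(mod):
            scorers = {"self": {g: float(m) for g, m in M.items()}}
            for col in ("score_average", "score_max", "score_sum"):
                scorers[col] = mod[col].to_dict()
            result.roc = roc_evaluate(scorers, cd_set, genes=gene_ids)
            result.roc.to_csv(out / "roc_auc.tsv", sep="\t")

    # --- complementarity
    if "complement" in stages:
        coding_map = {g: set(sub["sample"])
                      for g, sub in cohort.coding_variants.groupby("gene")}
        regulatory_map = {g: set(s) for g, s in rec["samples"].items()}
        records, tests = group_comparison(
            coding_map, regulatory_map, cohort.ppi, cd_set, td_set,
            max_background_pairs=cfg.max_background_pairs,
            seed=cfg.seed % (2 ** 31))
        result.complementarity = records
        result.complementarity_tests = tests
        records.to_csv(out / "complementarity.tsv", sep="\t", index=False)
        tests.to_csv(out / "complementarity_tests.tsv", sep="\t", index=False)
        if cd_set:
            lead = sorted(cd_set)[0]
            mat = exclusivity_matrix(lead, td_set, coding_map,
                                     regulatory_map, samples, k=5)
            mat.to_csv(out / "exclusivity_matrix.tsv", sep="\t")
    return result
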