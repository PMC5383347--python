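"""Readers and writers for the tabular and sequence formats of the pipeline.

Conventions: coordinates are 0-based half-open in memory (BED/BEDPE
native); variant tables and GTF are 1-based on disk and converted at this
boundary.  PWMs use MEME minimal motif format (via Bio.motifs); genomes are
plain FASTA (via Bio.SeqIO).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interactome import (ChromatinInteraction, Gene, GenomicInterval,
                          RegulatoryRegion, EnhancerPromoterMap)
from .motif_disruption import BASES, PWM

VARIANT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]


# -- variants ----------------------------------------------------------------


def read_variants(path) -> pd.DataFrame:
    """Tab-separated (sample, chrom, pos[1-based], ref, alt) -> 0-based df."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str,
                                            "pos": np.int64})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    df = df[VARIANT_COLUMNS].copy()
    df["pos"] -= 1
    return df


def write_variants(df: pd.DataFrame, path) -> None:
    out = df[VARIANT_COLUMNS].copy()
    out["pos"] += 1
    out.to_csv(path, sep="\t", index=False)


# -- BED / BEDPE -------------------------------------------------------------


def read_bed(path) -> List[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bedpe(path, support_column: int = 7) -> List[ChromatinInteraction]:
    """BEDPE with the source label in the name column (7th, 0-based 6) and
    the support value in ``support_column`` (0-based; default the score)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"BEDPE line has {len(f)} < 8 columns")
            source = f[6]
            support = float(f[support_column])
            if source == "ChIA-PET":
                support = int(support)
            out.append(ChromatinInteraction(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                GenomicInterval(f[3], int(f[4]), int(f[5])),
                source, support))
    return out


def write_bedpe(interactions: Iterable[ChromatinInteraction], path) -> None:
    with open(path, "w") as fh:
        for ia in interactions:
            a, b = ia.anchor1, ia.anchor2
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t"
                     f"{b.chrom}\t{b.start}\t{b.end}\t"
                     f"{ia.source}\t{ia.support:g}\t.\t.\n")


# -- GTF ---------------------------------------------------------------------


def read_gtf_genes(path) -> List[Gene]:
    """Minimal GTF reader: gene records with gene_id / gene_type attributes;
    only protein-coding genes are returned."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = {}
            for part in f[8].strip().split(";"):
                part = part.strip()
                if part:
                    k, _, v = part.partition(" ")
                    attrs[k] = v.strip('"')
            if attrs.get("gene_type", "protein_coding") != "protein_coding":
                continue
            genes.append(Gene(attrs["gene_id"], f[0], int(f[3]) - 1, int(f[4]),
                              f[6]))
    return genes


def write_gtf_genes(genes: Iterable[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\tcisrec\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t"
                     f'gene_id "{g.gene_id}"; gene_type "protein_coding";\n')


# -- FASTA -------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


# -- MEME minimal motifs -----------------------------------------------------


def read_meme(path) -> List[PWM]:
    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)])
        bg = np.array([m.background[b] for b in BASES])
        bg = bg / bg.sum()
        out.append(PWM(m.name or m.consensus, mat, background=bg))
    return out


def write_meme(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
                 "Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites: parsers that reconstitute integer counts keep
            # the probabilities to ~1e-6
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                     f"nsites= 1000000 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# -- networks ----------------------------------------------------------------


def read_edgelist(path, directed: bool = False):
    """Two-column (source, target) or three-column (with weight) edge list."""
    import networkx as nx

    g = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                g.add_edge(f[0], f[1], weight=float(f[2]))
            else:
                g.add_edge(f[0], f[1])
    return g


def write_edgelist(g, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in g.edges(data=True):
            if "weight" in data:
                fh.write(f"{u}\t{v}\t{data['weight']:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


# -- enhancer-promoter map ---------------------------------------------------


def write_ep_map(ep_map: EnhancerPromoterMap, path) -> None:
    """Tab-separated (gene_id, chrom, start, end, role, sources)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\trole\tsources\n")
        for g in ep_map.genes():
            for r in ep_map.intervals(g):
                iv = r.interval
                fh.write(f"{g}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{r.role}\t"
                         f"{','.join(sorted(r.sources))}\n")


def read_ep_map(path) -> EnhancerPromoterMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    assignments: Dict[str, List[RegulatoryRegion]] = {}
    for row in df.itertuples(index=False):
        assignments.setdefault(row.gene_id, []).append(RegulatoryRegion(
            GenomicInterval(row.chrom, row.start, row.end), row.role,
            frozenset(str(row.sources).split(","))))
    return EnhancerPromoterMap(assignments)


# -- coding variants and gene lists ------------------------------------------


def read_coding_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"gene": str, "sample": str, "position": np.int64,
                              "consequence": str})


def write_coding_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
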