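"""Readers and writers for the package's file dialects.

FASTA through Biopython; gene models as minimal GFF3 (feature type
``gene``, 1-based inclusive on disk, 0-based half-open in memory);
genotype matrices, truth tables, QC reports, maps and placements as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage_map import LinkageGroup
from .physical_map import ProbePlacement
from .synthetic_data import CrossResult, ProbeSet, SyntheticGenome


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genes_gff3(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genome.genes.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\tdartmap\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                (
                    attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                    parts[0],
                    int(parts[3]) - 1,
                    int(parts[4]),
                    parts[6],
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def write_genotypes_tsv(cross: CrossResult, path: str | Path) -> None:
    cross.genotypes.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)


def write_truth_map_tsv(cross: CrossResult, path: str | Path) -> None:
    cross.truth.to_csv(path, sep="\t")


def write_probe_truth_tsv(probes: ProbeSet, path: str | Path) -> None:
    probes.truth.to_csv(path, sep="\t", index=False)


def write_map_tsv(groups: list[LinkageGroup], path: str | Path) -> None:
    pd.concat([g.to_frame() for g in groups], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_map_tsv(path: str | Path) -> list[LinkageGroup]:
    import numpy as np

    frame = pd.read_csv(path, sep="\t")
    groups = []
    for gid, sub in frame.groupby("group", sort=False):
        sub = sub.sort_values("cm")
        groups.append(
            LinkageGroup(
                group_id=str(gid),
                markers=list(sub["marker_id"]),
                positions_cm=np.asarray(sub["cm"], dtype=float),
                mode=str(sub["mode"].iloc[0]),
            )
        )
    return groups


def write_placements_tsv(placements: list[ProbePlacement], path: str | Path) -> None:
    rows = []
    for p in placements:
        primary = p.primary_hit
        rows.append(
            {
                "probe_id": p.probe_id,
                "status": p.status,
                "scaffold": primary.scaffold_id if primary else "",
                "start": primary.start if primary else "",
                "end": primary.end if primary else "",
                "strand": primary.strand if primary else "",
                "score": primary.score if primary else "",
                "second_scaffold": p.secondary_hit.scaffold_id if p.secondary_hit else "",
                "second_start": p.secondary_hit.start if p.secondary_hit else "",
                "inter_hit_distance": (
                    p.inter_hit_distance if p.inter_hit_distance is not None else ""
                ),
                "n_retained": p.n_retained,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
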