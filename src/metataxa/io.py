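"""File-format plumbing: FASTA, taxonomy/role TSVs, result tables, newick.

Read headers carry their sample as ``>sampleID|readID``. Taxonomy rows are
``taxon_id<TAB>phylum;class;order;family;genus;species``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .opu_slp import AbundanceTable, OPURecord
from .synthetic_data import RANKS, ReadRecord, ReadSet, ReferenceDB, ReferenceTaxon


def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=f"{r.sample_id}|{r.read_id}", description="")
        for r in reads
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_reads_fasta(path: str | Path) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, _, read_id = rec.id.partition("|")
        if not read_id:
            sample, read_id = "sample1", rec.id
        reads.append(ReadRecord(sample, read_id, str(rec.seq).upper(), None))
    return ReadSet(reads)


def write_reference(db: ReferenceDB, fasta: str | Path, taxonomy: str | Path) -> None:
    recs = [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in db]
    SeqIO.write(recs, str(fasta), "fasta")
    with open(taxonomy, "w") as fh:
        fh.write("taxon_id\tlineage\tis_type_strain\n")
        for t in db:
            fh.write(f"{t.id}\t{';'.join(t.lineage)}\t{int(t.is_type_strain)}\n")


def read_reference(fasta: str | Path, taxonomy: str | Path) -> ReferenceDB:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    tax = pd.read_csv(taxonomy, sep="\t", dtype=str)
    taxa = {}
    for _, row in tax.iterrows():
        tid = row["taxon_id"]
        if tid not in seqs:
            continue
        lineage = tuple(row["lineage"].split(";"))
        if len(lineage) != len(RANKS):
            raise ValueError(f"{tid}: lineage must have {len(RANKS)} ranks")
        taxa[tid] = ReferenceTaxon(
            id=tid, lineage=lineage, sequence=seqs[tid],
            is_type_strain=bool(int(row.get("is_type_strain", 1))),
        )
    return ReferenceDB(taxa)


def write_truth(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tsource_taxon\tis_chimera\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.sample_id}\t{r.source_taxon or 'NA'}\t{int(r.is_chimera)}\n"
            )


def write_otu_map(otus, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\totu_id\n")
        for o in otus:
            for read_id, _ in o.members:
                fh.write(f"{read_id}\t{o.otu_id}\n")


def write_opu_table(table: AbundanceTable, path: str | Path) -> None:
    meta = pd.DataFrame(
        {
            rec.opu_id: {
                "category": rec.category,
                "new_taxon_rank": rec.new_taxon_rank or "NA",
                "anchor": rec.anchor_ref_id or "NA",
                "anchor_identity": round(rec.anchor_identity, 6),
                "lineage": ";".join(rec.assigned_lineage),
            }
            for rec in table.records
        }
    ).T
    out = meta.join(table.counts)
    out.index.name = "opu_id"
    out.to_csv(path, sep="\t")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")
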