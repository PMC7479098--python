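"""OPU delineation, categorization and the SLP x sample abundance table.

An OPU (operational phylogenetic unit) is the smallest monophyletic clade
containing query (OTU representative) leaves together with their closest
reference sequence — a type strain whenever possible. Each OPU is treated
as one species-level phylotype (SLP) and categorized as:

* ``classified_species`` — anchored to a type strain at > 98.7% identity;
* ``potential_new_species`` — an independent lineage within a clear genus;
* ``potential_new_taxon`` — the anchoring clade spans several genera (or
  higher ranks); the new rank is one below the lowest rank at which the
  clade's reference leaves still agree.

The manual tree inspection of classical OPU work is formalized here as the
smallest-anchored-clade plus rank-homogeneity rules. Rank homogeneity is
evaluated on reference leaves only; query leaves never vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .reads_to_otus import OTU, pairwise_identity
from .synthetic_data import RANKS, ReadSet, ReferenceDB

CATEGORIES = ("classified_species", "potential_new_species", "potential_new_taxon")
NEW_TAXON_RANKS = ("genus", "family", "order", "class", "phylum")


@dataclass
class OPURecord:
    opu_id: str
    member_otu_ids: list[str]
    anchor_ref_id: str | None = None
    anchor_identity: float = 0.0
    category: str | None = None
    new_taxon_rank: str | None = None
    assigned_lineage: tuple[str, ...] = ()
    representative: str = ""


@dataclass
class AbundanceTable:
    """Read counts per SLP (rows) and sample (columns)."""

    counts: pd.DataFrame
    records: list[OPURecord] = field(default_factory=list)

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def slp_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# clade search


def smallest_anchored_clade(
    tree: TreeNode, query_leaf: str, reference_ids: set[str]
) -> TreeNode:
    """Minimal ancestor of the query containing at least one reference leaf.

    The root-path is linear, so the minimal anchored node is unique; the
    "type strain whenever possible" preference acts through anchor choice
    within the clade, not through clade choice.
    """
    node = tree.find(query_leaf)
    while node.parent is not None:
        node = node.parent
        if any(l in reference_ids for l in node.subset()):
            return node
    if any(l in reference_ids for l in node.subset()):
        return node
    raise ValueError("tree contains no reference leaves")


def delineate_opus(
    tree: TreeNode, queries: list[str], reference_ids: set[str]
) -> list[tuple[TreeNode, list[str]]]:
    """Partition queries into OPUs by their smallest anchored clades.

    Two queries belong to one OPU exactly when their smallest anchored
    clades contain the same set of reference leaves — clades that coincide,
    or nest around the same references (e.g. two OTUs stacked on one type
    strain's terminal edge), merge; clades anchored to different or larger
    reference sets stay separate. The OPU clade is the outermost clade of
    the merged group. Returns (clade, member queries) pairs; every query
    belongs to exactly one OPU.
    """
    if not queries:
        return []
    clades = {q: smallest_anchored_clade(tree, q, reference_ids) for q in queries}
    anchor_sets = {
        q: frozenset(l for l in clades[q].subset() if l in reference_ids)
        for q in queries
    }
    groups: dict[frozenset, list[str]] = {}
    for q in queries:
        groups.setdefault(anchor_sets[q], []).append(q)
    out = []
    for members in groups.values():
        outer = max((clades[q] for q in members), key=lambda n: len(n.subset()))
        out.append((outer, sorted(members)))
    out.sort(key=lambda pair: pair[1][0])
    return out


# ---------------------------------------------------------------------------
# categorization


def categorize_opu(
    record: OPURecord,
    clade_reference_ids: list[str],
    db: ReferenceDB,
    species_threshold: float = 0.987,
) -> OPURecord:
    """Fill in category, rank and lineage from the anchoring clade.

    Requires ``record.anchor_ref_id`` and ``record.anchor_identity`` to be
    set (identity of the OPU representative to its anchor, by the
    pipeline's pairwise identity).
    """
    for rid in clade_reference_ids:
        if rid not in db.taxa:
            raise ValueError(f"missing lineage for reference taxon {rid!r}")
    anchor = db.taxa[record.anchor_ref_id] if record.anchor_ref_id else None
    lineages = [db.taxa[r].lineage for r in clade_reference_ids]
    if anchor is not None and anchor.is_type_strain and record.anchor_identity > species_threshold:
        record.category = "classified_species"
        record.new_taxon_rank = None
        record.assigned_lineage = anchor.lineage
        return record
    genera = {lin[4] for lin in lineages}
    if len(genera) == 1:
        record.category = "potential_new_species"
        record.new_taxon_rank = None
        record.assigned_lineage = lineages[0][:5]
        return record
    record.category = "potential_new_taxon"
    # lowest rank at which all clade references agree; new rank is one below
    for k in (3, 2, 1, 0):  # family, order, class, phylum
        if len({lin[: k + 1] for lin in lineages}) == 1:
            record.new_taxon_rank = RANKS[k + 1]
            record.assigned_lineage = lineages[0][: k + 1]
            return record
    record.new_taxon_rank = "phylum"
    record.assigned_lineage = ()
    return record


def call_opus(
    tree: TreeNode,
    otus: list[OTU],
    db: ReferenceDB,
    species_threshold: float = 0.987,
    min_otu_size: int = 1,
) -> list[OPURecord]:
    """Delineate and categorize OPUs for placed OTU representatives.

    The anchor is the clade's maximum-identity type strain when one is
    present, else its maximum-identity reference. OPU ids are assigned by
    decreasing total read count.
    """
    by_id = {o.otu_id: o for o in otus if o.size >= min_otu_size}
    tips = {t.name for t in tree.tips()}
    queries = [oid for oid in by_id if oid in tips]
    reference_ids = {t.id for t in db if t.id in tips}
    groups = delineate_opus(tree, queries, reference_ids)
    records = []
    for clade, members in groups:
        clade_refs = sorted(l for l in clade.subset() if l in reference_ids)
        largest = max(members, key=lambda m: (by_id[m].size, m))
        rep = by_id[largest].representative
        candidates = [r for r in clade_refs if db.taxa[r].is_type_strain] or clade_refs
        idents = {r: pairwise_identity(rep, db.taxa[r].sequence) for r in candidates}
        anchor = max(idents, key=lambda r: (idents[r], r))
        rec = OPURecord(
            opu_id="",
            member_otu_ids=members,
            anchor_ref_id=anchor,
            anchor_identity=idents[anchor],
            representative=rep,
        )
        categorize_opu(rec, clade_refs, db, species_threshold)
        records.append(rec)
    records.sort(key=lambda r: (-sum(by_id[m].size for m in r.member_otu_ids), r.member_otu_ids[0]))
    for i, rec in enumerate(records):
        rec.opu_id = f"OPU{i + 1:04d}"
    return records


# ---------------------------------------------------------------------------
# abundance table


def build_slp_table(
    opus: list[OPURecord], otus: list[OTU], reads: ReadSet
) -> AbundanceTable:
    """Tally retained reads into an SLP x sample count matrix.

    Every retained read must map to an OTU and every OTU to an OPU; rows
    are ordered by total abundance, descending.
    """
    otu_of_read: dict[str, str] = {}
    for o in otus:
        for read_id, _ in o.members:
            otu_of_read[read_id] = o.otu_id
    opu_of_otu: dict[str, str] = {}
    for rec in opus:
        for oid in rec.member_otu_ids:
            opu_of_otu[oid] = rec.opu_id
    samples = sorted({r.sample_id for r in reads})
    counts = {rec.opu_id: {s: 0 for s in samples} for rec in opus}
    unmapped = []
    for r in reads:
        otu_id = otu_of_read.get(r.read_id)
        opu_id = opu_of_otu.get(otu_id) if otu_id else None
        if opu_id is None:
            unmapped.append(r.read_id)
            continue
        counts[opu_id][r.sample_id] += 1
    if unmapped:
        raise ValueError(f"unmapped reads: {unmapped[:10]}" +
                         (f" (+{len(unmapped) - 10} more)" if len(unmapped) > 10 else ""))
    df = pd.DataFrame.from_dict(counts, orient="index").astype(int)
    df = df.loc[df.sum(axis=1).sort_values(ascending=False, kind="stable").index, samples]
    return AbundanceTable(counts=df, records=list(opus))
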