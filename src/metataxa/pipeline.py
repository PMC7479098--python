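"""End-to-end orchestration: synthetic data -> reads -> OTUs -> tree -> SLPs.

`run_pipeline` wires the stage modules together under one configuration and
master seed. Each stochastic stage receives its own derived seed so stages
can be regenerated independently. Reference sequences are trimmed to the
same positional window as the reads, so the whole analysis shares one
coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reads_to_otus as r2o
from . import reference_tree as rtree
from .opu_slp import AbundanceTable, OPURecord, build_slp_table, call_opus
from .synthetic_data import (
    CommunityModel,
    CommunitySet,
    ReadSet,
    ReferenceDB,
    ReferenceTaxon,
    build_reference_db,
    sample_reads,
    simulate_communities,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for a synthetic run (defaults: the desk-scale
    benchmark of 40 samples at depth 2,000 over a 72-species reference
    taxonomy with 10 planted novel species and 4 planted novel genera)."""

    # reference taxonomy
    n_phyla: int = 2
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 3
    species_per_genus: int = 6
    stem_genera_per_family: int = 1
    sequence_length: int = 1443
    # communities
    n_samples: int = 40
    frac_type_P: float = 0.625
    tier_fractions: tuple[float, float, float] = (0.68, 0.225, 0.095)
    novelty_fractions: tuple[float, float] = (10.0 / 72.0, 1.0)
    community_model: CommunityModel = field(default_factory=CommunityModel)
    # reads
    depth: int = 2000
    error_rate: float = 0.00159
    chimera_rate: float = 0.0
    # QC / clustering
    trim_window: tuple[int, int] = (10, 1490)
    min_len: int = 1000
    max_len: int = 1600
    chimera_margin: float = 0.02
    otu_threshold: float = 0.987
    min_otu_size: int = 1
    # placement / OPU
    min_conservation: float = 0.30
    species_threshold: float = 0.987


@dataclass
class PipelineResult:
    config: PipelineConfig
    seed: int
    db: ReferenceDB  # full ground truth (novelty included)
    analysis_db: ReferenceDB  # window-trimmed public references
    communities: CommunitySet
    raw_reads: ReadSet
    retained_reads: ReadSet
    filter_report: "r2o.FilterReport"
    otus: list
    alignment: "rtree.AlignedMatrix"
    distances: "np.ndarray"
    tree: object
    opus: list[OPURecord]
    table: AbundanceTable


def _trimmed_db(db: ReferenceDB, window: tuple[int, int]) -> ReferenceDB:
    start, end = window
    taxa = {}
    for t in db:
        taxa[t.id] = ReferenceTaxon(
            id=t.id, lineage=t.lineage, sequence=t.sequence[start - 1 : end],
            is_type_strain=t.is_type_strain, stem_genus=t.stem_genus,
        )
    return ReferenceDB(taxa, outgroup_id=db.outgroup_id)


def run_pipeline(config: PipelineConfig = PipelineConfig(), seed: int = 0) -> PipelineResult:
    rng = np.random.default_rng(seed)
    s_db, s_comm, s_reads = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))

    db = build_reference_db(
        config.n_phyla, config.genera_per_family, config.species_per_genus, s_db,
        classes_per_phylum=config.classes_per_phylum,
        orders_per_class=config.orders_per_class,
        families_per_order=config.families_per_order,
        stem_genera_per_family=config.stem_genera_per_family,
        length=config.sequence_length,
    )
    communities = simulate_communities(
        db, config.n_samples, config.frac_type_P, config.tier_fractions,
        config.novelty_fractions, s_comm, model=config.community_model,
    )
    raw_reads = sample_reads(
        communities, db, config.depth, config.error_rate, config.chimera_rate, s_reads
    )

    qc_reads, qc_report = r2o.quality_filter(
        raw_reads, config.min_len, config.max_len, config.trim_window
    )
    public = communities.public_reference(db)
    analysis_db = _trimmed_db(public, config.trim_window)
    retained, chim_report = r2o.chimera_filter(
        qc_reads, analysis_db, margin=config.chimera_margin
    )
    report = qc_report.combine(chim_report)

    otus = r2o.greedy_cluster(retained, threshold=config.otu_threshold)

    refs = {t.id: t.sequence for t in analysis_db}
    queries = {o.otu_id: o.representative for o in otus}
    aln = rtree.align_profiles(refs, queries)
    aln = rtree.conservation_mask(aln, config.min_conservation)
    dist = rtree.distance_matrix(aln)

    ref_ids = list(refs)
    tree = rtree.nj_tree(dist.loc[ref_ids, ref_ids], analysis_db.outgroup_id)
    order = [o.otu_id for o in sorted(otus, key=lambda o: (-o.size, o.otu_id))]
    rtree.place_queries(tree, dist, order)

    opus = call_opus(
        tree, otus, analysis_db,
        species_threshold=config.species_threshold,
        min_otu_size=config.min_otu_size,
    )
    table = build_slp_table(opus, otus, retained)
    return PipelineResult(
        config=config, seed=seed, db=db, analysis_db=analysis_db,
        communities=communities, raw_reads=raw_reads, retained_reads=retained,
        filter_report=report, otus=otus, alignment=aln, distances=dist,
        tree=tree, opus=opus, table=table,
    )
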