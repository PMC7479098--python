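"""Synthetic reference databases, community profiles and 16S read sets.

The generator emulates the statistical structure a species-level
metataxonomic analysis assumes, so every downstream stage can be exercised
without external downloads:

* a hierarchical reference taxonomy (phylum > class > order > family >
  genus > species) whose type-strain sequences are evolved along the
  taxonomy with rank-calibrated divergence, so that congeneric species and
  confamilial genera land in fixed identity bands straddling the 98.7%
  species threshold;
* two planted community types (``P`` and ``B``), each dominated by a
  distinct taxon and reinforced by a guild of co-varying taxa — the
  enterotype-like structure seen in human gut cohorts;
* three prevalence tiers of taxa (low / medium / high occupancy);
* reads copied from their source with i.i.d. per-base substitutions at the
  platform error rate (default 0.159%), optionally spliced two-parent
  chimeras;
* planted novelty: taxa present in the reads but withheld from the emitted
  reference database ("potentially new" species and genera).

All sequences in one database share a common length and diverge by
substitutions only; indels, quality scores and PCR bias are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _seq

RANKS = ("phylum", "class", "order", "family", "genus", "species")

OUTGROUP_ID = "OUTGROUP"


class BandError(ValueError):
    """A divergence band requested of the generator could not be realized."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReferenceTaxon:
    """One reference 16S sequence with its full six-rank lineage."""

    id: str
    lineage: tuple[str, ...]  # (phylum, class, order, family, genus, species)
    sequence: str
    is_type_strain: bool = True
    stem_genus: bool = False  # lineage branched from a family stem, not the crown

    def __post_init__(self):
        if len(self.lineage) != len(RANKS) or any(not r for r in self.lineage):
            raise ValueError(f"{self.id}: lineage must have {len(RANKS)} non-empty ranks")
        if not _seq.is_acgt(self.sequence):
            raise ValueError(f"{self.id}: sequence must be non-empty over A/C/G/T")

    @property
    def genus(self) -> str:
        return self.lineage[4]

    @property
    def species(self) -> str:
        return self.lineage[5]


@dataclass
class ReferenceDB:
    """Container of reference taxa; the taxonomic ground truth."""

    taxa: dict[str, ReferenceTaxon]
    outgroup_id: str = OUTGROUP_ID

    def __post_init__(self):
        if len({t.id for t in self.taxa.values()}) != len(self.taxa):
            raise ValueError("taxon ids must be unique")

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa.values())

    @property
    def species_ids(self) -> list[str]:
        """Ids of non-outgroup taxa, in insertion order."""
        return [t.id for t in self.taxa.values() if t.id != self.outgroup_id]

    def subset(self, exclude: set[str]) -> "ReferenceDB":
        kept = {tid: t for tid, t in self.taxa.items() if tid not in exclude}
        return ReferenceDB(kept, outgroup_id=self.outgroup_id)

    def sequences(self) -> dict[str, str]:
        return {t.id: t.sequence for t in self.taxa.values()}


@dataclass
class CommunityProfile:
    """Realized composition of one sample."""

    sample_id: str
    type_label: str  # "P" or "B"
    composition: dict[str, float]  # taxon_id -> relative abundance, sums to 1

    def __post_init__(self):
        vals = np.array(list(self.composition.values()))
        if vals.size == 0 or (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: composition must be >=0 and sum to 1")


@dataclass
class CommunitySet:
    """A set of community profiles plus the planted ground truth."""

    profiles: list[CommunityProfile]
    tiers: dict[str, str]  # taxon_id -> low / medium / high
    dominants: dict[str, str]  # type_label -> taxon_id
    guilds: dict[str, list[str]]  # type_label -> guild taxon ids
    withheld_taxa: set[str] = field(default_factory=set)
    withheld_species: list[str] = field(default_factory=list)
    withheld_genera: list[str] = field(default_factory=list)  # genus labels

    def public_reference(self, db: ReferenceDB) -> ReferenceDB:
        """The reference database visible to the pipeline (novelty withheld)."""
        return db.subset(self.withheld_taxa)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]


@dataclass(frozen=True)
class ReadRecord:
    sample_id: str
    read_id: str
    sequence: str
    source_taxon: str | None  # None for chimeras
    is_chimera: bool = False
    chimera_parents: tuple[str, str] | None = None


@dataclass
class ReadSet:
    reads: list[ReadRecord]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def by_sample(self) -> dict[str, list[ReadRecord]]:
        out: dict[str, list[ReadRecord]] = {}
        for r in self.reads:
            out.setdefault(r.sample_id, []).append(r)
        return out


# ---------------------------------------------------------------------------
# generator parameters


@dataclass(frozen=True)
class BranchRates:
    """Per-edge substitution probabilities, one mutation round per edge.

    Chosen analytically so that sibling-species identities fall inside
    ``DivergenceBands.congeneric`` and cross-genus identities inside
    ``DivergenceBands.confamilial`` (back-mutation accounted for via the
    Jukes-Cantor eigenvalue 1 - 4r/3 per round).
    """

    phylum: float = 0.03
    class_: float = 0.015
    order: float = 0.02
    family: float = 0.04
    genus: float = 0.036
    species: float = 0.0225
    novel_genus: float = 0.0585  # stem-genus own descent (genus + species scale)
    outgroup: float = 0.12


@dataclass(frozen=True)
class DivergenceBands:
    """Identity bands the generated reference must realize (config values)."""

    species_threshold: float = 0.987
    congeneric: tuple[float, float] = (0.92, 0.987)
    confamilial: tuple[float, float] = (0.86, 0.92)


@dataclass(frozen=True)
class CommunityModel:
    """Log-normal abundance model with tiered occupancy and typed guilds.

    ``mu_*`` are log-scale expected weights (sigma fixed at 1.0); occupancy
    is the per-sample Bernoulli presence probability that places realized
    prevalence inside the <10% / 10-60% / >60% bands in expectation.
    """

    sigma: float = 1.0
    occupancy: dict = field(
        default_factory=lambda: {"low": 0.03, "medium": 0.35, "high": 0.9}
    )
    mu: dict = field(
        default_factory=lambda: {
            "low": 0.0,
            "medium": float(np.log(3.0)),
            "high": float(np.log(8.0)),
        }
    )
    mu_dominant: float = float(np.log(80.0))
    sigma_dominant: float = 0.5  # dominants are consistently high: that is what
    # defines a community type, so their load varies less than ordinary taxa
    dominant_other_occupancy: float = 0.15
    mu_dominant_other: float = float(np.log(2.0))
    guild_size: int = 8
    guild_boost: float = 1.0  # added to (subtracted from) mu in own (other) type
    guild_occupancy_own: dict = field(
        default_factory=lambda: {"medium": 0.6, "high": 1.0}
    )
    guild_occupancy_other: dict = field(
        default_factory=lambda: {"medium": 0.05, "high": 0.1}
    )


# ---------------------------------------------------------------------------
# operations


def build_reference_db(
    n_phyla: int,
    genera_per_family: int,
    species_per_genus: int,
    seed: int,
    *,
    classes_per_phylum: int = 1,
    orders_per_class: int = 1,
    families_per_order: int = 1,
    stem_genera_per_family: int = 0,
    length: int = 1443,
    rates: BranchRates = BranchRates(),
    bands: DivergenceBands = DivergenceBands(),
    validate: bool = True,
) -> ReferenceDB:
    """Evolve a rank-structured reference database from one ancestral 16S.

    Each taxonomic edge applies one round of i.i.d. substitutions at the
    rank's :class:`BranchRates` probability. Stem genera branch from the
    midpoint of their family's stem edge, so that (once withheld from the
    emitted references) their reads place basal to the family crown — the
    planted "potentially new genus" case. A distant outgroup taxon is always
    included for rooting.
    """
    for name, v in [
        ("n_phyla", n_phyla),
        ("genera_per_family", genera_per_family),
        ("species_per_genus", species_per_genus),
        ("classes_per_phylum", classes_per_phylum),
        ("orders_per_class", orders_per_class),
        ("families_per_order", families_per_order),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    # band realization is stochastic; resample deterministically on a band
    # miss and only reject parameter sets that fail repeatedly
    last_err: BandError | None = None
    for attempt in range(10 if validate else 1):
        rng = np.random.default_rng(seed if attempt == 0 else [seed, attempt])
        try:
            return _build_reference_db_once(
                rng, n_phyla, genera_per_family, species_per_genus,
                classes_per_phylum, orders_per_class, families_per_order,
                stem_genera_per_family, length, rates, bands, validate,
            )
        except BandError as err:
            last_err = err
    raise BandError(
        f"divergence bands not realizable for these parameters: {last_err}"
    )


def _build_reference_db_once(
    rng, n_phyla, genera_per_family, species_per_genus, classes_per_phylum,
    orders_per_class, families_per_order, stem_genera_per_family, length,
    rates, bands, validate,
) -> ReferenceDB:
    root = _seq.random_seq(length, rng)
    taxa: dict[str, ReferenceTaxon] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter:04d}"

    for p in range(1, n_phyla + 1):
        phy = _seq.mutate(root, rates.phylum, rng)
        phy_name = f"Phylum{p}"
        for c in range(1, classes_per_phylum + 1):
            cls = _seq.mutate(phy, rates.class_, rng)
            cls_name = f"{phy_name}_Class{c}"
            for o in range(1, orders_per_class + 1):
                ordr = _seq.mutate(cls, rates.order, rng)
                ord_name = f"{cls_name}_Order{o}"
                for f in range(1, families_per_order + 1):
                    # family stem split in two so stem genera branch mid-edge
                    stem_mid = _seq.mutate(ordr, rates.family / 2.0, rng)
                    crown = _seq.mutate(stem_mid, rates.family / 2.0, rng)
                    fam_name = f"{ord_name}_Family{f}"
                    for g in range(1, genera_per_family + 1):
                        gen = _seq.mutate(crown, rates.genus, rng)
                        gen_name = f"{fam_name}_Genus{g}"
                        for s in range(1, species_per_genus + 1):
                            sp = _seq.mutate(gen, rates.species, rng)
                            tid = new_id()
                            taxa[tid] = ReferenceTaxon(
                                id=tid,
                                lineage=(
                                    phy_name, cls_name, ord_name, fam_name,
                                    gen_name, f"{gen_name}_sp{s}",
                                ),
                                sequence=_seq.decode(sp),
                            )
                    for g in range(1, stem_genera_per_family + 1):
                        sg = _seq.mutate(stem_mid, rates.novel_genus, rng)
                        gen_name = f"{fam_name}_StemGenus{g}"
                        tid = new_id()
                        taxa[tid] = ReferenceTaxon(
                            id=tid,
                            lineage=(
                                phy_name, cls_name, ord_name, fam_name,
                                gen_name, f"{gen_name}_sp1",
                            ),
                            sequence=_seq.decode(sg),
                            stem_genus=True,
                        )
    og = _seq.mutate(root, rates.outgroup, rng)
    taxa[OUTGROUP_ID] = ReferenceTaxon(
        id=OUTGROUP_ID,
        lineage=(
            "PhylumOut", "PhylumOut_Class1", "PhylumOut_Order1",
            "PhylumOut_Family1", "PhylumOut_Genus1", "PhylumOut_Genus1_sp1",
        ),
        sequence=_seq.decode(og),
    )
    db = ReferenceDB(taxa)
    if validate:
        _validate_bands(db, bands, rng)
    return db


def _validate_bands(db: ReferenceDB, bands: DivergenceBands, rng: np.random.Generator) -> None:
    """Check realized identities against the configured divergence bands.

    Identities are gapless (all generated sequences are collinear); a random
    subsample is re-measured with the pipeline's full ``pairwise_identity``
    to guard the equivalence.
    """
    from .reads_to_otus import pairwise_identity

    crown = [t for t in db if t.id != db.outgroup_id and not t.stem_genus]
    enc = {t.id: _seq.encode(t.sequence) for t in crown}
    congeneric, confamilial = [], []
    for i, a in enumerate(crown):
        for b in crown[i + 1:]:
            if a.lineage[3] != b.lineage[3]:
                continue
            ident = _seq.hamming_identity(enc[a.id], enc[b.id])
            (congeneric if a.genus == b.genus else confamilial).append((a.id, b.id, ident))
    for name, lo_hi, pairs in [
        ("congeneric", bands.congeneric, congeneric),
        ("confamilial", bands.confamilial, confamilial),
    ]:
        lo, hi = lo_hi
        for aid, bid, ident in pairs:
            if not (lo < ident < hi):
                raise BandError(
                    f"{name} band ({lo}, {hi}) not realized: "
                    f"identity({aid}, {bid}) = {ident:.4f}"
                )
    # spot-check with the full alignment identity: it must land in the same
    # band, and the gapless shortcut must track it closely (gaps can only
    # nudge identity at divergences far below the species threshold)
    for name, lo_hi, pairs in [
        ("congeneric", bands.congeneric, congeneric),
        ("confamilial", bands.confamilial, confamilial),
    ]:
        if not pairs:
            continue
        lo, hi = lo_hi
        idx = rng.choice(len(pairs), size=min(3, len(pairs)), replace=False)
        for k in idx:
            aid, bid, ident = pairs[k]
            full = pairwise_identity(db.taxa[aid].sequence, db.taxa[bid].sequence)
            if not (lo < full < hi) or abs(full - ident) > 0.005:
                raise BandError(
                    f"{name} band ({lo}, {hi}) not realized by pairwise_identity: "
                    f"identity({aid}, {bid}) = {full:.4f} (gapless {ident:.4f})"
                )


def simulate_communities(
    db: ReferenceDB,
    n_samples: int,
    frac_type_P: float = 0.5,
    tier_fractions: tuple[float, float, float] = (0.68, 0.225, 0.095),
    novelty_fractions: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    *,
    model: CommunityModel = CommunityModel(),
) -> CommunitySet:
    """Draw per-sample compositions for two planted community types.

    Tier membership is fixed per taxon; per-sample presence is Bernoulli at
    the tier's occupancy and present taxa receive log-normal weights which
    are normalized to a composition. Each type has exactly one dominant
    taxon (largest expected abundance) plus a guild of taxa boosted in its
    own type and suppressed in the other. ``novelty_fractions = (f_species,
    f_stem_genera)`` selects taxa whose sequences appear in reads but are
    withheld from the emitted reference database.
    """
    if not 0.0 <= frac_type_P <= 1.0:
        raise ValueError("frac_type_P must be in [0, 1]")
    if abs(sum(tier_fractions) - 1.0) > 1e-9:
        raise ValueError("tier_fractions must sum to 1")
    if any(not 0.0 <= f <= 1.0 for f in novelty_fractions):
        raise ValueError("novelty_fractions must be in [0, 1]")
    n_P = int(round(frac_type_P * n_samples))
    n_B = n_samples - n_P
    if n_P < 1 or n_B < 1:
        raise ValueError("each community type needs at least one sample")
    rng = np.random.default_rng(seed)

    taxa = [db.taxa[t] for t in db.species_ids]
    crown = [t for t in taxa if not t.stem_genus]
    stem = [t for t in taxa if t.stem_genus]

    # --- planted novelty -------------------------------------------------
    f_sp, f_gen = novelty_fractions
    n_novel_sp = int(round(f_sp * len(crown)))
    genera: dict[str, list[ReferenceTaxon]] = {}
    for t in crown:
        genera.setdefault(t.genus, []).append(t)
    # at most one withheld species per genus keeps every genus anchored
    if n_novel_sp > len(genera):
        raise ValueError("cannot withhold more than one species per genus")
    withheld_species: list[str] = []
    for gname in rng.permutation(sorted(genera))[:n_novel_sp]:
        members = genera[gname]
        if len(members) < 2:
            continue  # a singleton genus would lose its anchor entirely
        withheld_species.append(members[int(rng.integers(len(members)))].id)
    n_novel_gen = int(round(f_gen * len(stem)))
    if f_gen > 0 and not stem:
        raise ValueError(
            "novelty_fractions[1] > 0 requires stem genera "
            "(build_reference_db(..., stem_genera_per_family >= 1))"
        )
    withheld_genus_taxa = [t.id for t in stem[:n_novel_gen]]
    withheld_genera = sorted({db.taxa[t].genus for t in withheld_genus_taxa})
    withheld = set(withheld_species) | set(withheld_genus_taxa)

    # --- dominants, tiers, guilds ----------------------------------------
    candidates = [t.id for t in crown if t.id not in withheld]
    if len(candidates) < 2:
        raise ValueError("need at least two non-withheld crown species for dominants")
    dom_idx = rng.choice(len(candidates), size=2, replace=False)
    dominants = {"P": candidates[dom_idx[0]], "B": candidates[dom_idx[1]]}

    others = [t.id for t in taxa if t.id not in dominants.values()]
    perm = rng.permutation(others)
    n_low = int(round(tier_fractions[0] * len(others)))
    n_med = int(round(tier_fractions[1] * len(others)))
    base_tier = {t: "high" for t in dominants.values()}
    for i, tid in enumerate(perm):
        base_tier[tid] = "low" if i < n_low else ("medium" if i < n_low + n_med else "high")

    high_pool = [t for t in perm if base_tier[t] == "high"]
    med_pool = [t for t in perm if base_tier[t] == "medium"]
    gsz = model.guild_size
    half_h = len(high_pool) // 2
    guild_P = list(high_pool[:half_h][:gsz])
    guild_B = list(high_pool[half_h:][:gsz])
    # top up from the medium tier, disjointly: P from the front, B from the back
    need_P, need_B = gsz - len(guild_P), gsz - len(guild_B)
    if need_P + need_B > len(med_pool):
        need_P = min(need_P, len(med_pool) // 2)
        need_B = min(need_B, len(med_pool) - need_P)
    guild_P += med_pool[:need_P]
    if need_B:
        guild_B += med_pool[len(med_pool) - need_B:]
    guilds = {"P": guild_P, "B": guild_B}

    # --- per-sample draws --------------------------------------------------
    guild_of = {}
    for lab, members in guilds.items():
        for tid in members:
            guild_of[tid] = lab

    def occ_mu_sigma(tid: str, lab: str) -> tuple[float, float, float]:
        other = "B" if lab == "P" else "P"
        tier = base_tier[tid]
        if tid == dominants[lab]:
            return 1.0, model.mu_dominant, model.sigma_dominant
        if tid == dominants[other]:
            return model.dominant_other_occupancy, model.mu_dominant_other, model.sigma
        if guild_of.get(tid) == lab:
            return (model.guild_occupancy_own[tier],
                    model.mu[tier] + model.guild_boost, model.sigma)
        if guild_of.get(tid) == other:
            return (model.guild_occupancy_other[tier],
                    model.mu[tier] - model.guild_boost, model.sigma)
        return model.occupancy[tier], model.mu[tier], model.sigma

    # the planted tier label is the band of the taxon's expected overall
    # prevalence under the type mixture (for untyped taxa this equals the
    # base tier's occupancy band by construction)
    frac_P = n_P / n_samples
    tiers: dict[str, str] = {}
    all_ids = [t.id for t in taxa]
    for tid in all_ids:
        p_exp = (frac_P * occ_mu_sigma(tid, "P")[0]
                 + (1.0 - frac_P) * occ_mu_sigma(tid, "B")[0])
        tiers[tid] = "low" if p_exp < 0.10 else ("medium" if p_exp <= 0.60 else "high")

    labels = ["P"] * n_P + ["B"] * n_B
    profiles = []
    for i, lab in enumerate(labels):
        present: list[str] = []
        mus: list[float] = []
        sigmas: list[float] = []
        for tid in all_ids:
            p, mu, sg = occ_mu_sigma(tid, lab)
            if rng.random() < p:
                present.append(tid)
                mus.append(mu)
                sigmas.append(sg)
        w = np.exp(np.array(mus) + np.array(sigmas) * rng.standard_normal(len(mus)))
        w /= w.sum()
        profiles.append(
            CommunityProfile(
                sample_id=f"S{i + 1:03d}",
                type_label=lab,
                composition=dict(zip(present, w.tolist())),
            )
        )
    return CommunitySet(
        profiles=profiles,
        tiers=tiers,
        dominants=dominants,
        guilds=guilds,
        withheld_taxa=withheld,
        withheld_species=withheld_species,
        withheld_genera=withheld_genera,
    )


def sample_reads(
    communities: CommunitySet | list[CommunityProfile],
    db: ReferenceDB,
    depth: int,
    error_rate: float = 0.00159,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw ``depth`` reads per sample with per-base substitution errors.

    Reads are multinomially allocated across the sample's composition; each
    read copies its source sequence with i.i.d. substitutions at
    ``error_rate`` per base. With probability ``chimera_rate`` a read is
    instead a two-parent splice at a uniform breakpoint in [300, 1200].
    True provenance is recorded for every read.
    """
    profiles = communities.profiles if isinstance(communities, CommunitySet) else communities
    if not profiles:
        raise ValueError("empty profile set")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for name, r in [("error_rate", error_rate), ("chimera_rate", chimera_rate)]:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    enc = {tid: _seq.encode(s) for tid, s in db.sequences().items()}
    reads: list[ReadRecord] = []
    for prof in profiles:
        if not prof.composition:
            raise ValueError(f"{prof.sample_id}: empty composition")
        tids = list(prof.composition)
        probs = np.array([prof.composition[t] for t in tids])
        counts = rng.multinomial(depth, probs / probs.sum())
        n_read = 0
        for tid, k in zip(tids, counts):
            src = enc[tid]
            for _ in range(int(k)):
                n_read += 1
                rid = f"{prof.sample_id}_r{n_read:05d}"
                if chimera_rate > 0.0 and rng.random() < chimera_rate and len(tids) >= 2:
                    other = tids[int(rng.integers(len(tids)))]
                    while other == tid and len(tids) > 1:
                        other = tids[int(rng.integers(len(tids)))]
                    L = min(src.size, enc[other].size)
                    bp = int(rng.integers(300, min(1200, L - 1) + 1))
                    spliced = np.concatenate([src[:bp], enc[other][bp:]])
                    seq = _seq.mutate(spliced, error_rate, rng) if error_rate else spliced
                    reads.append(
                        ReadRecord(prof.sample_id, rid, _seq.decode(seq), None,
                                   is_chimera=True, chimera_parents=(tid, other))
                    )
                else:
                    seq = _seq.mutate(src, error_rate, rng) if error_rate else src
                    reads.append(ReadRecord(prof.sample_id, rid, _seq.decode(seq), tid))
    return ReadSet(reads)
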