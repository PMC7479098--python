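"""Ground-truth scoring of synthetic pipeline runs.

Every function here compares pipeline output against the planted truth
carried by the synthetic generator: read provenance, withheld (novel)
taxa, prevalence tiers, community types and dominants. These are the
quantities the package's validation and acceptance reporting are built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import compositional_stats as comp
from . import prevalence_abundance as prev
from ._seq import encode, hamming_identity
from .pipeline import PipelineResult


def measured_error_rate_pct(result: PipelineResult, max_reads: int = 20000) -> float:
    """Mean per-base mismatch of non-chimeric raw reads vs their source, %."""
    db = result.db
    total = n = 0
    for r in result.raw_reads:
        if r.is_chimera or r.source_taxon is None:
            continue
        src = db.taxa[r.source_taxon].sequence
        total += 1.0 - hamming_identity(encode(r.sequence), encode(src))
        n += 1
        if n >= max_reads:
            break
    return 100.0 * total / max(n, 1)


def opu_truth_table(result: PipelineResult) -> pd.DataFrame:
    """Per OPU: called category vs the planted one, and the true species.

    The OPU's true source is the majority source taxon of its member reads;
    the planted category follows from whether that taxon was withheld as a
    novel species, belongs to a withheld (stem) genus, or is a public
    reference.
    """
    read_source = {r.read_id: r.source_taxon for r in result.retained_reads}
    otu_by_id = {o.otu_id: o for o in result.otus}
    comm = result.communities
    novel_species = set(comm.withheld_species)
    novel_genus_taxa = {
        t for t in comm.withheld_taxa if result.db.taxa[t].genus in comm.withheld_genera
    }
    rows = {}
    for rec in result.opus:
        sources: dict[str | None, int] = {}
        for oid in rec.member_otu_ids:
            for read_id, _ in otu_by_id[oid].members:
                s = read_source.get(read_id)
                sources[s] = sources.get(s, 0) + 1
        majority = max(sources, key=lambda s: (sources[s], str(s)))
        if majority is None:
            planted = "chimera"
            true_species = None
        elif majority in novel_genus_taxa:
            planted = "potential_new_taxon"
            true_species = result.db.taxa[majority].species
        elif majority in novel_species:
            planted = "potential_new_species"
            true_species = result.db.taxa[majority].species
        else:
            planted = "classified_species"
            true_species = result.db.taxa[majority].species
        called_species = rec.assigned_lineage[5] if len(rec.assigned_lineage) == 6 else None
        rows[rec.opu_id] = {
            "called": rec.category,
            "planted": planted,
            "true_taxon": majority,
            "true_species": true_species,
            "called_species": called_species,
            "anchor_identity": rec.anchor_identity,
            "new_taxon_rank": rec.new_taxon_rank,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def category_recovery(result: PipelineResult) -> float:
    """Fraction of OPUs whose called category equals the planted one."""
    t = opu_truth_table(result)
    t = t[t["planted"] != "chimera"]
    return float((t["called"] == t["planted"]).mean())


def species_name_accuracy(result: PipelineResult) -> float:
    """Among OPUs called classified_species, fraction naming the true species."""
    t = opu_truth_table(result)
    c = t[t["called"] == "classified_species"]
    if c.empty:
        return float("nan")
    return float((c["called_species"] == c["true_species"]).mean())


def tier_recovery(result: PipelineResult) -> float:
    """Fraction of SLPs whose realized prevalence stratum matches the
    planted tier of their true source taxon."""
    t = opu_truth_table(result)
    p = prev.prevalence(result.table)
    strata = prev.stratify(p.prevalence)
    tiers = result.communities.tiers
    hits = total = 0
    for opu_id, row in t.iterrows():
        taxon = row["true_taxon"]
        if taxon is None or taxon not in tiers:
            continue
        total += 1
        hits += int(strata[opu_id] == tiers[taxon])
    return hits / total if total else float("nan")


@dataclass
class TypeRecovery:
    ari: float
    mean_silhouette: float
    permanova_p: float
    permanova_r2: float
    dominants_on_top: bool
    labels: pd.Series
    clr_matrix: pd.DataFrame
    distances: pd.DataFrame


def two_type_recovery(
    result: PipelineResult, k: int = 2, n_perm: int = 1000, seed: int = 0
) -> TypeRecovery:
    """Run the compositional typing layer and score it against the planted
    P/B community types."""
    counts = comp.from_table(result.table)
    clr_m = comp.clr(comp.replace_zeros(counts))
    dist = comp.aitchison_distance(clr_m)
    typing = comp.ward_cluster(dist, k=k)
    truth = pd.Series(
        {p.sample_id: p.type_label for p in result.communities.profiles}
    ).loc[counts.index]
    ari = adjusted_rand_score(truth.to_numpy(), typing.labels.to_numpy())
    pmv = comp.permanova(dist, truth, n_perm=n_perm, seed=seed)

    t = opu_truth_table(result)
    rel = prev.relative_abundance(result.table)
    on_top = True
    for cl in sorted(typing.labels.unique()):
        samples = typing.labels.index[typing.labels == cl]
        top_slp = rel[samples].mean(axis=1).idxmax()
        major_type = truth.loc[samples].mode().iloc[0]
        dominant_taxon = result.communities.dominants[major_type]
        on_top &= t.loc[top_slp, "true_taxon"] == dominant_taxon
    return TypeRecovery(
        ari=float(ari), mean_silhouette=typing.mean_silhouette,
        permanova_p=pmv.p_value, permanova_r2=pmv.r2,
        dominants_on_top=bool(on_top), labels=typing.labels,
        clr_matrix=clr_m, distances=dist,
    )


def dominant_slp_ids(result: PipelineResult) -> dict[str, str]:
    """Map community type -> the SLP whose true source is that type's dominant."""
    t = opu_truth_table(result)
    out = {}
    for label, taxon in result.communities.dominants.items():
        hits = t.index[t["true_taxon"] == taxon]
        if len(hits):
            out[label] = hits[0]
    return out


# ---------------------------------------------------------------------------
# null-model calibration


def permanova_type1_rate(
    n_replicates: int = 1000, n_samples: int = 20, n_dims: int = 10,
    n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of perMANOVA at level alpha when labels carry no signal."""
    rng = np.random.default_rng(seed)
    labels = np.array(["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2))
    hits = 0
    for rep in range(n_replicates):
        X = rng.standard_normal((n_samples, n_dims))
        idx = [f"s{i}" for i in range(n_samples)]
        D = comp.aitchison_distance(pd.DataFrame(X, index=idx))
        fac = pd.Series(rng.permutation(labels), index=idx)
        res = comp.permanova(D, fac, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += res.p_value <= alpha
    return hits / n_replicates


def _null_counts(
    rng: np.random.Generator, n_samples: int, n_slps: int, depth: int,
    biological_sigma: float = 1.0,
) -> pd.DataFrame:
    """Null community counts: one base composition, per-sample log-normal
    biological noise, multinomial sequencing."""
    base = np.exp(rng.standard_normal(n_slps))
    counts = np.empty((n_samples, n_slps), dtype=int)
    for i in range(n_samples):
        w = base * np.exp(biological_sigma * rng.standard_normal(n_slps))
        counts[i] = rng.multinomial(depth, w / w.sum())
    return pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"x{j}" for j in range(n_slps)],
    )


def da_type1_rate(
    n_replicates: int = 1000, n_per_group: int = 10, n_slps: int = 20,
    depth: int = 2000, n_mc: int = 256, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Per-test type-I error of the instance-averaged Welch p under the null."""
    rng = np.random.default_rng(seed)
    groups = pd.Series(
        ["a"] * n_per_group + ["b"] * n_per_group,
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    hits = total = 0
    for rep in range(n_replicates):
        counts = _null_counts(rng, 2 * n_per_group, n_slps, depth)
        res = comp.dirichlet_mc_da(
            counts, groups, n_mc=n_mc, seed=int(rng.integers(2**31 - 1))
        )
        hits += int((res.table["t_p"] < alpha).sum())
        total += n_slps
    return hits / total


def da_planted_shift_effect(
    fold: float = 8.0, n_per_group: int = 20, n_slps: int = 20,
    depth: int = 2000, n_mc: int = 256, seed: int = 0,
) -> tuple[float, bool]:
    """Effect size and flag for one SLP shifted ``fold``-x in group b."""
    rng = np.random.default_rng(seed)
    counts = _null_counts(rng, 2 * n_per_group, n_slps, depth)
    # rescale the first SLP in the second group's samples
    shifted = counts.copy()
    bidx = shifted.index[n_per_group:]
    shifted.loc[bidx, shifted.columns[0]] = (
        shifted.loc[bidx, shifted.columns[0]] * fold
    ).astype(int)
    groups = pd.Series(
        ["a"] * n_per_group + ["b"] * n_per_group, index=shifted.index
    )
    res = comp.dirichlet_mc_da(shifted, groups, n_mc=n_mc, seed=seed + 1)
    row = res.table.iloc[0]
    return float(row["effect"]), bool(row["significant"])
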