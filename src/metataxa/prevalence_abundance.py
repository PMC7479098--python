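"""Relative abundance, prevalence strata and per-individual carriage.

Prevalence is the percentage of samples in which an SLP is detected
(count > 0 by default); SLPs are stratified into low (<10%), medium
(10-60%, boundaries inclusive) and high (>60%) prevalence groups. Role
annotations (probiotic / commensal / potential pathogen) are consumed as
externally curated species lists and matched by exact species name on
classified SLPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .opu_slp import AbundanceTable

GROUPS = ("low", "medium", "high")
ROLES = ("probiotic", "commensal", "potential_pathogen", "unassigned")


@dataclass
class PrevalenceResult:
    """Per-SLP prevalence, mean relative abundance and 5% histogram."""

    prevalence: pd.Series  # percent of samples, per SLP
    mean_relative_abundance: pd.Series  # percent of reads, per SLP (pooled)
    histogram: pd.DataFrame  # index: bin label; columns: n_slps, total_abundance_pct


def relative_abundance(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample column to percent (sums to 100)."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    return counts / sums * 100.0


def prevalence(
    table: AbundanceTable | pd.DataFrame, min_count: int = 1
) -> PrevalenceResult:
    """Percent of samples carrying each SLP, plus the 5%-interval histogram.

    Bins are [0,5), [5,10), ..., [95,100]; abundance per bin is the pooled
    percent of total reads contributed by the bin's SLPs.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    present = counts >= min_count
    prev = present.sum(axis=1) / counts.shape[1] * 100.0
    pooled = counts.sum(axis=1) / counts.to_numpy().sum() * 100.0
    edges = np.arange(0, 105, 5)
    idx = np.clip(np.digitize(prev, edges[1:-1], right=False), 0, len(edges) - 2)
    labels = [f"[{edges[i]},{edges[i+1]}{']' if i == len(edges) - 2 else ')'}"
              for i in range(len(edges) - 1)]
    hist = pd.DataFrame(
        {"n_slps": 0, "total_abundance_pct": 0.0}, index=pd.Index(labels, name="bin")
    )
    for slp, b in zip(prev.index, idx):
        hist.iloc[b, 0] += 1
        hist.iloc[b, 1] += pooled[slp]
    return PrevalenceResult(prevalence=prev, mean_relative_abundance=pooled, histogram=hist)


def stratify(prev: pd.Series) -> pd.Series:
    """Label SLPs low (<10), medium (10-60 inclusive) or high (>60) percent."""
    if ((prev < 0) | (prev > 100)).any():
        raise ValueError("prevalence must be within [0, 100]")
    out = pd.Series("medium", index=prev.index, dtype=object)
    out[prev < 10.0] = "low"
    out[prev > 60.0] = "high"
    return out


def per_sample_summary(
    table: AbundanceTable | pd.DataFrame,
    groups: pd.Series,
    roles: dict[str, str] | None = None,
    species_of: dict[str, str] | None = None,
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-sample carriage: SLPs detected, counts per prevalence group,
    counts and summed relative abundance per role.

    ``groups`` maps SLP id -> prevalence group; ``roles`` maps species name
    -> role; ``species_of`` maps SLP id -> species name for classified SLPs
    (role matching is by exact species name). Unknown species in the role
    list raise a warning, not an error.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    roles = roles or {}
    species_of = species_of or {}
    known = set(species_of.values())
    stray = sorted(set(roles) - known)
    if stray and known:
        warnings.warn(f"role list names unknown species: {stray[:5]}")
    rel = relative_abundance(counts)
    present = counts >= min_count
    slp_role = pd.Series(
        [roles.get(species_of.get(slp, ""), "unassigned") for slp in counts.index],
        index=counts.index,
    )
    rows = {}
    for s in counts.columns:
        mask = present[s]
        det = counts.index[mask]
        row = {"n_slps": int(mask.sum())}
        for g in GROUPS:
            row[f"n_{g}"] = int((groups[det] == g).sum())
        for role in ROLES:
            sel = det[(slp_role[det] == role)]
            row[f"n_{role}"] = len(sel)
            row[f"abundance_{role}_pct"] = float(rel.loc[sel, s].sum())
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def group_abundance_summary(
    table: AbundanceTable | pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per prevalence group: SLP count and relative abundance, both pooled
    across all reads and as the mean of per-sample percentages."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    rel = relative_abundance(counts)
    total = counts.to_numpy().sum()
    rows = {}
    for g in GROUPS:
        slps = groups.index[groups == g]
        rows[g] = {
            "n_slps": len(slps),
            "pooled_abundance_pct": float(counts.loc[slps].to_numpy().sum() / total * 100.0),
            "mean_sample_abundance_pct": float(rel.loc[slps].sum(axis=0).mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
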