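"""Read QC, chimera removal and greedy centroid OTU clustering at 98.7%.

The identity definition used throughout the pipeline (clustering, anchor
identity, simulation validation) is fixed here: global affine-gap alignment
(match +1, mismatch -1, gap open -2, gap extend -1), identity = matches /
alignment columns with terminal gap columns excluded.

Clustering follows greedy centroid practice: unique sequences are processed
in decreasing multiplicity (ties broken by lexicographic sequence order);
a sequence joins the first centroid at >= threshold identity, else founds a
new centroid. On substitution-only inputs (the synthetic generator, and
any amplicon set without indels) an ``assume_ungapped`` fast path replaces
the aligner with vectorized Hamming comparisons; the two routes agree and
are asserted equivalent in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from . import _seq
from .synthetic_data import ReadRecord, ReadSet

REPORT_COLUMNS = ["input", "removed_ambiguous", "removed_length", "removed_chimera", "retained"]


@dataclass
class FilterReport:
    """Per-sample read accounting for one or more filtering stages."""

    counts: pd.DataFrame  # index: sample_id; columns: REPORT_COLUMNS

    def __post_init__(self):
        missing = [c for c in REPORT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"missing report columns: {missing}")
        removed = self.counts[REPORT_COLUMNS[1:-1]].sum(axis=1)
        if not (self.counts["input"] == removed + self.counts["retained"]).all():
            raise ValueError("input != removed + retained in filter report")

    @staticmethod
    def from_counts(rows: dict[str, dict[str, int]]) -> "FilterReport":
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=REPORT_COLUMNS).fillna(0).astype(int)
        return FilterReport(df)

    def combine(self, other: "FilterReport") -> "FilterReport":
        """Stack two sequential stages into one accounting table."""
        idx = self.counts.index.union(other.counts.index)
        a = self.counts.reindex(idx, fill_value=0)
        b = other.counts.reindex(idx, fill_value=0)
        out = a.copy()
        for c in REPORT_COLUMNS[1:-1]:
            out[c] = a[c] + b[c]
        out["retained"] = b["retained"]
        return FilterReport(out)


@dataclass
class OTU:
    """A cluster of reads at the species-discrimination identity threshold."""

    otu_id: str
    members: list[tuple[str, str]]  # (read_id, sample_id)
    seq_multiplicity: dict[str, int]  # member sequence -> read count
    representative: str

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# pairwise identity

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -2
_ALIGNER.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of ``a`` and ``b``.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1. Identity is
    matches / alignment columns, where columns spanned by terminal gaps are
    excluded. Symmetric by construction (the pair is ordered canonically
    before aligning).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if b < a:
        a, b = b, a
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    ta, qa = aln.aligned
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(ta, qa):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)  # internal gap columns
        sa, sb = a[ts:te], b[qs:qe]
        matches += sum(x == y for x, y in zip(sa, sb))
        columns += te - ts
        prev_t, prev_q = te, qe
    if columns == 0:
        return 0.0
    return matches / columns


# ---------------------------------------------------------------------------
# quality filter


def quality_filter(
    reads: ReadSet,
    min_len: int = 1000,
    max_len: int = 1600,
    trim_window: tuple[int, int] = (10, 1490),
) -> tuple[ReadSet, FilterReport]:
    """Drop ambiguous-base reads, trim to a positional window, bound lengths.

    ``trim_window`` is 1-based inclusive; reads are truncated to that
    positional range, and reads whose post-trim length falls outside
    ``[min_len, max_len]`` are removed. Input order is preserved.
    """
    start, end = trim_window
    if start < 1 or start >= end:
        raise ValueError(f"invalid trim window {trim_window}")
    kept: list[ReadRecord] = []
    rows: dict[str, dict[str, int]] = {}
    for r in reads:
        row = rows.setdefault(
            r.sample_id, {c: 0 for c in REPORT_COLUMNS}
        )
        row["input"] += 1
        if not _seq.is_acgt(r.sequence):
            row["removed_ambiguous"] += 1
            continue
        trimmed = r.sequence[start - 1 : end]
        if not (min_len <= len(trimmed) <= max_len):
            row["removed_length"] += 1
            continue
        row["retained"] += 1
        kept.append(
            ReadRecord(r.sample_id, r.read_id, trimmed, r.source_taxon,
                       r.is_chimera, r.chimera_parents)
        )
    return ReadSet(kept), FilterReport.from_counts(rows)


# ---------------------------------------------------------------------------
# chimera filter


def _resolve_refs(references) -> dict[str, str]:
    if hasattr(references, "sequences"):
        return references.sequences()
    return dict(references)


def chimera_filter(
    reads: ReadSet,
    references,
    margin: float = 0.02,
    grid: int = 50,
    assume_ungapped: bool | str = "auto",
) -> tuple[ReadSet, FilterReport]:
    """Reference-based bimera check.

    A read is flagged when some two-parent split (left prefix from parent A,
    right suffix from parent B, breakpoint scanned on a ``grid``-nt lattice)
    beats the best single-parent identity by at least ``margin``. Flagged
    reads are removed. This is a simplified stand-in for de-novo chimera
    detection and can be disabled upstream by passing ``margin >= 1``.
    """
    refs = _resolve_refs(references)
    if not refs:
        raise ValueError("references must be non-empty")
    seqs = [r.sequence for r in reads]
    if not seqs:
        return ReadSet([]), FilterReport.from_counts({})
    lengths = {len(s) for s in seqs} | {len(s) for s in refs.values()}
    if assume_ungapped == "auto":
        assume_ungapped = len(lengths) == 1
    if assume_ungapped:
        flagged = _bimera_flags_ungapped(seqs, list(refs.values()), margin, grid)
    else:
        flagged = _bimera_flags_aligned(seqs, list(refs.values()), margin, grid)
    kept: list[ReadRecord] = []
    rows: dict[str, dict[str, int]] = {}
    for r, bad in zip(reads, flagged):
        row = rows.setdefault(r.sample_id, {c: 0 for c in REPORT_COLUMNS})
        row["input"] += 1
        if bad:
            row["removed_chimera"] += 1
        else:
            row["retained"] += 1
            kept.append(r)
    return ReadSet(kept), FilterReport.from_counts(rows)


def _bimera_flags_ungapped(
    seqs: list[str], refs: list[str], margin: float, grid: int
) -> np.ndarray:
    """Vectorized bimera scores for collinear (equal-length) inputs."""
    uniq = sorted(set(seqs))
    pos = {s: i for i, s in enumerate(uniq)}
    U = _seq.encode_block(uniq)
    R = _seq.encode_block(refs)
    L = U.shape[1]
    bps = np.arange(grid, L, grid)
    flags = np.empty(len(uniq), dtype=bool)
    chunk = 128
    for lo in range(0, len(uniq), chunk):
        block = U[lo : lo + chunk]
        neq = block[:, None, :] != R[None, :, :]  # (n, R, L)
        cum = np.cumsum(neq, axis=2, dtype=np.int32)
        total = cum[:, :, -1]
        pref = cum[:, :, bps - 1]  # mismatches strictly before each breakpoint
        suff = total[:, :, None] - pref
        two = (pref.min(axis=1) + suff.min(axis=1)).min(axis=1)
        single = total.min(axis=1)
        flags[lo : lo + chunk] = (single - two) / L >= margin
    return np.array([flags[pos[s]] for s in seqs])


def _bimera_flags_aligned(
    seqs: list[str], refs: list[str], margin: float, grid: int
) -> np.ndarray:
    """General-path bimera scores via per-reference alignment match profiles."""
    flags = []
    for s in seqs:
        L = len(s)
        profiles = np.zeros((len(refs), L), dtype=bool)
        for j, ref in enumerate(refs):
            aln = _ALIGNER.align(s, ref)[0]
            for (ts, te), (qs, qe) in zip(*aln.aligned):
                seg = np.frombuffer(s[ts:te].encode(), np.uint8) == np.frombuffer(
                    ref[qs:qe].encode(), np.uint8
                )
                profiles[j, ts:te] = seg
        matches = profiles.sum(axis=1)
        single = matches.max() / L
        bps = np.arange(grid, L, grid)
        pref = np.cumsum(profiles, axis=1)[:, bps - 1]
        suff = matches[:, None] - pref
        two = (pref.max(axis=0) + suff.max(axis=0)).max() / L
        flags.append(two - single >= margin)
    return np.array(flags)


# ---------------------------------------------------------------------------
# greedy centroid clustering


class _CentroidStore:
    """Growing per-length buffers of centroid sequences for Hamming scans."""

    def __init__(self):
        self.order: list[tuple[int, int]] = []  # (length, row) in founding order
        self.buffers: dict[int, np.ndarray] = {}
        self.used: dict[int, int] = {}
        self.global_index: dict[int, list[int]] = {}  # length -> founding indices

    def add(self, enc: np.ndarray) -> None:
        L = enc.size
        if L not in self.buffers:
            self.buffers[L] = np.empty((16, L), dtype=np.uint8)
            self.used[L] = 0
            self.global_index[L] = []
        if self.used[L] == self.buffers[L].shape[0]:
            grown = np.empty((self.used[L] * 2, L), dtype=np.uint8)
            grown[: self.used[L]] = self.buffers[L]
            self.buffers[L] = grown
        self.buffers[L][self.used[L]] = enc
        self.global_index[L].append(len(self.order))
        self.order.append((L, self.used[L]))
        self.used[L] += 1

    def first_match_ungapped(self, enc: np.ndarray, threshold: float) -> int | None:
        """Founding index of the first centroid with identity >= threshold."""
        L = enc.size
        if L not in self.buffers or self.used[L] == 0:
            return None
        M = self.buffers[L][: self.used[L]]
        ident = 1.0 - np.count_nonzero(M != enc[None, :], axis=1) / L
        hits = np.nonzero(ident >= threshold)[0]
        if hits.size == 0:
            return None
        return self.global_index[L][int(hits[0])]


def greedy_cluster(
    reads: ReadSet,
    threshold: float = 0.987,
    assume_ungapped: bool | str = "auto",
    inclusive: bool = True,
) -> list[OTU]:
    """Greedy centroid clustering of reads at an identity threshold.

    Unique sequences are processed in decreasing read multiplicity (ties by
    lexicographic sequence order). A sequence joins the first existing
    centroid whose identity meets the threshold (``>=`` when ``inclusive``,
    the default; strict ``>`` otherwise); otherwise it founds a new
    centroid. OTU ids are assigned by decreasing size after clustering.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    groups: dict[str, list[tuple[str, str]]] = {}
    for r in reads:
        groups.setdefault(r.sequence, []).append((r.read_id, r.sample_id))
    uniq = sorted(groups, key=lambda s: (-len(groups[s]), s))
    if assume_ungapped == "auto":
        assume_ungapped = len({len(s) for s in uniq}) <= 1

    def accepts(ident: float) -> bool:
        return ident >= threshold if inclusive else ident > threshold

    centroid_seqs: list[str] = []
    assignment: dict[str, int] = {}
    if assume_ungapped:
        store = _CentroidStore()
        eps = 1e-12  # guard float round-off at the inclusive boundary
        thr = threshold - eps if inclusive else threshold + eps
        for s in uniq:
            enc = _seq.encode(s)
            hit = store.first_match_ungapped(enc, thr)
            if hit is None:
                assignment[s] = len(centroid_seqs)
                centroid_seqs.append(s)
                store.add(enc)
            else:
                assignment[s] = hit
    else:
        for s in uniq:
            for ci, c in enumerate(centroid_seqs):
                if accepts(pairwise_identity(s, c)):
                    assignment[s] = ci
                    break
            else:
                assignment[s] = len(centroid_seqs)
                centroid_seqs.append(s)

    clusters: dict[int, list[str]] = {}
    for s, ci in assignment.items():
        clusters.setdefault(ci, []).append(s)
    otus = []
    for ci, seqs in clusters.items():
        mult = {s: len(groups[s]) for s in seqs}
        members = [m for s in sorted(seqs) for m in groups[s]]
        otus.append(OTU("", members, mult, representative=""))
    otus.sort(key=lambda o: (-o.size, min(o.seq_multiplicity)))
    for i, o in enumerate(otus):
        o.otu_id = f"OTU{i + 1:05d}"
        o.representative = pick_representative(o)
    return otus


def pick_representative(otu: OTU) -> str:
    """The member sequence with the highest read multiplicity.

    Ties are broken by lexicographically smallest sequence.
    """
    if not otu.seq_multiplicity:
        raise ValueError("empty OTU")
    return min(otu.seq_multiplicity, key=lambda s: (-otu.seq_multiplicity[s], s))
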