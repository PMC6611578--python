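"""Raw amplicon reads to a filtered MOTU read-count table.

Stages, in order: pair merging -> per-read quality filter ->
dereplication -> length / global minimum-count filter -> per-sample
relative-abundance filter -> greedy centroid clustering -> exclusion of
non-target MOTUs (reference-match failures, configured non-prey taxa,
blank contaminants).

Threshold semantics (all strict/inclusive boundaries matter):
  * overlap >= 10 bases, mismatch fraction <= 8%
  * quality: fraction of bases with Phred > 30 must be >= 0.90
  * keep sequences of length >= 149 with global count >= 5
  * within each sample, drop counts below 0.1 permille of the sample total
  * cluster joining at Hamming distance <= 1
  * reference match similarity < 40% -> excluded as no_match
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRead",
    "MotuTable",
    "TaxonRecord",
    "DEFAULT_EXCLUSION_TAXA",
    "merge_read_pair",
    "quality_filter",
    "dereplicate",
    "length_min_count_filter",
    "within_sample_relative_filter",
    "cluster_motus",
    "exclude_nontarget",
    "exclusion_percentages",
    "run_table_pipeline",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRead:
    """A single read: id, bases over {A,C,G,T,N}, per-base Phred scores."""

    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRead":
        return SequenceRead(
            id=self.id,
            bases=self.bases.translate(_COMPLEMENT)[::-1],
            qualities=self.qualities[::-1],
        )


@dataclass
class MotuTable:
    """Integer read counts of MOTUs per sample.

    ``counts`` is samples x MOTUs with unique row/column labels;
    ``centroids`` optionally maps MOTU id -> representative sequence.
    """

    counts: pd.DataFrame
    centroids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("sample and MOTU labels must be unique")
        if (c.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def drop_empty_motus(self) -> "MotuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return MotuTable(
            counts=self.counts[keep].copy(),
            centroids={m: s for m, s in self.centroids.items() if m in set(keep)},
        )


EXCLUSION_REASONS = (
    "none",
    "no_match",
    "non_animal",
    "guano_fauna",
    "secondary_prey",
    "blank_contaminant",
)


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic path of one MOTU plus reference-match similarity."""

    motu_id: str
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    match_similarity: float = 0.0
    excluded_reason: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.match_similarity <= 100:
            raise ValueError("match similarity must be a percentage in [0, 100]")
        if self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")

    @property
    def rank_path(self) -> tuple[str, ...]:
        return (self.class_, self.order, self.family, self.genus, self.species)

    @property
    def identification_level(self) -> str:
        ranks = ("class", "order", "family", "genus", "species")
        level = "unidentified"
        for rank, name in zip(ranks, self.rank_path):
            if name:
                level = rank
        return level


# Default non-target taxa, editable via config file (see cli_io formats):
# non-animal groups, guano-visiting arthropods, and secondary prey.
DEFAULT_EXCLUSION_TAXA: dict[str, tuple[str, ...]] = {
    "non_animal": ("Bacteria", "Enterobacteriaceae", "Algae", "Fungi", "Rotifera"),
    "guano_fauna": ("Acari", "Machilidae", "Anobiidae", "Dermestidae"),
    "secondary_prey": ("Gastropoda",),
}


def merge_read_pair(
    fwd: SequenceRead,
    rev: SequenceRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.08,
) -> SequenceRead | None:
    """Merge a read pair on their overlapping ends, or ``None`` on failure.

    The reverse read is reverse-complemented; ungapped suffix(fwd) /
    prefix(revcomp) overlaps of length >= ``min_overlap`` are scored and
    the one with the lowest mismatch fraction (ties: longest) wins,
    provided its mismatch fraction is <= ``max_mismatch_frac``. Consensus
    at overlap mismatches keeps the higher-quality base (tie: forward);
    overlap quality is the maximum of the two reads.
    """
    if len(fwd) == 0 or len(rev) == 0:
        raise ValueError("cannot merge empty reads")
    rc = rev.reverse_complement()
    best = None  # (mismatch_frac, -overlap_len, overlap_len)
    for olap in range(min_overlap, min(len(fwd), len(rc)) + 1):
        f_tail = fwd.bases[len(fwd) - olap :]
        r_head = rc.bases[:olap]
        mism = sum(1 for a, b in zip(f_tail, r_head) if a != b)
        frac = mism / olap
        if frac > max_mismatch_frac:
            continue
        cand = (frac, -olap, olap)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    olap = best[2]
    off = len(fwd) - olap
    bases, quals = [], []
    for i in range(olap):
        fb, fq = fwd.bases[off + i], fwd.qualities[off + i]
        rb, rq = rc.bases[i], rc.qualities[i]
        if fb == rb:
            bases.append(fb)
        else:
            bases.append(rb if rq > fq else fb)
        quals.append(max(fq, rq))
    return SequenceRead(
        id=fwd.id,
        bases=fwd.bases[:off] + "".join(bases) + rc.bases[olap:],
        qualities=fwd.qualities[:off] + tuple(quals) + rc.qualities[olap:],
    )


def quality_filter(read: SequenceRead, min_q: int = 30, min_frac: float = 0.90) -> bool:
    """True iff at least ``min_frac`` of bases have quality strictly > ``min_q``."""
    if len(read) == 0:
        raise ValueError("quality filter undefined for an empty read")
    good = sum(1 for q in read.qualities if q > min_q)
    return good / len(read) >= min_frac


def dereplicate(reads_by_sample: dict[str, list[str]]) -> pd.DataFrame:
    """Collapse identical sequences; rows = samples, columns = unique sequences."""
    seqs: dict[str, dict[str, int]] = defaultdict(dict)
    for sample, seq_list in reads_by_sample.items():
        for seq in seq_list:
            seqs[seq][sample] = seqs[seq].get(sample, 0) + 1
    table = pd.DataFrame.from_dict(seqs, dtype=float).fillna(0).astype(int)
    return table.reindex(index=list(reads_by_sample), fill_value=0)


def length_min_count_filter(
    table: pd.DataFrame, min_len: int = 149, min_reads: int = 5
) -> pd.DataFrame:
    """Keep sequences of length >= ``min_len`` with global count >= ``min_reads``.

    Columns are the sequences themselves (or objects with ``len``); counts
    are summed study-wide, matching global dereplication.
    """
    totals = table.sum(axis=0)
    keep = [s for s in table.columns if len(s) >= min_len and totals[s] >= min_reads]
    return table[keep].copy()


def within_sample_relative_filter(table: pd.DataFrame, threshold: float = 1e-4) -> pd.DataFrame:
    """Zero out counts below ``threshold`` of each sample's total, per sample."""
    mat = table.to_numpy(dtype=float).copy()
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mat / totals, 0.0)
    mat[frac < threshold] = 0
    return pd.DataFrame(mat.astype(int), index=table.index, columns=table.columns)


def _hamming_like(a: str, b: str) -> int:
    """Mismatches over the shared prefix plus the length difference."""
    if len(a) > len(b):
        a, b = b, a
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return mism + (len(b) - len(a))


def cluster_motus(table: pd.DataFrame, max_mismatch: int = 1) -> MotuTable:
    """Greedy abundance-sorted centroid clustering of unique sequences.

    Sequences are processed by descending global count (ties broken
    lexicographically); each joins the first existing centroid within
    ``max_mismatch`` mismatches, else founds a new MOTU. MOTU counts are
    the per-sample sums over members; MOTU ids are ``motu0001`` ... in
    centroid discovery order.
    """
    totals = table.sum(axis=0)
    ordered = sorted(table.columns, key=lambda s: (-totals[s], s))
    centroids: list[str] = []
    assignment: dict[str, int] = {}
    for seq in ordered:
        for idx, cen in enumerate(centroids):
            if _hamming_like(seq, cen) <= max_mismatch:
                assignment[seq] = idx
                break
        else:
            assignment[seq] = len(centroids)
            centroids.append(seq)
    width = max(4, len(str(len(centroids))))
    ids = [f"motu{i + 1:0{width}d}" for i in range(len(centroids))]
    counts = pd.DataFrame(0, index=table.index, columns=ids)
    for seq, idx in assignment.items():
        counts[ids[idx]] += table[seq]
    return MotuTable(counts=counts, centroids=dict(zip(ids, centroids)))


def exclude_nontarget(
    table: MotuTable,
    taxonomy: dict[str, TaxonRecord],
    blank_sample_ids=(),
    min_similarity: float = 40.0,
    exclusion_taxa: dict[str, tuple[str, ...]] | None = None,
) -> tuple[MotuTable, pd.DataFrame]:
    """Drop non-target MOTUs and blank samples; report every removal.

    Removal reasons, checked in order: ``no_match`` (similarity strictly
    below ``min_similarity``; missing taxonomy counts as no match),
    ``non_animal`` / ``guano_fauna`` / ``secondary_prey`` (any rank name in
    the configured exclusion lists), ``blank_contaminant`` (any read in
    any blank sample). Returns the cleaned table (blanks removed,
    empty columns dropped) and a report with columns
    ``motu_id, reason, similarity``.
    """
    if exclusion_taxa is None:
        exclusion_taxa = DEFAULT_EXCLUSION_TAXA
    blanks = list(blank_sample_ids)
    missing_blanks = [b for b in blanks if b not in table.counts.index]
    if missing_blanks:
        raise KeyError(f"blank sample ids not in table: {missing_blanks}")

    taxon_sets = {
        cat: {name.lower() for name in names} for cat, names in exclusion_taxa.items()
    }
    in_blank = set()
    if blanks:
        blank_counts = table.counts.loc[blanks]
        in_blank = set(blank_counts.columns[(blank_counts > 0).any(axis=0)])

    rows = []
    for motu in table.motu_ids:
        rec = taxonomy.get(motu)
        reason = "none"
        sim = rec.match_similarity if rec is not None else float("nan")
        if rec is None or rec.match_similarity < min_similarity:
            reason = "no_match"
        else:
            path = {name.lower() for name in rec.rank_path if name}
            for cat in ("non_animal", "guano_fauna", "secondary_prey"):
                if path & taxon_sets.get(cat, set()):
                    reason = cat
                    break
        if reason == "none" and motu in in_blank:
            reason = "blank_contaminant"
        if reason != "none":
            rows.append({"motu_id": motu, "reason": reason, "similarity": sim})

    report = pd.DataFrame(rows, columns=["motu_id", "reason", "similarity"])
    removed = set(report["motu_id"])
    kept_samples = [s for s in table.sample_ids if s not in set(blanks)]
    kept_motus = [m for m in table.motu_ids if m not in removed]
    cleaned = MotuTable(
        counts=table.counts.loc[kept_samples, kept_motus].copy(),
        centroids={m: s for m, s in table.centroids.items() if m in set(kept_motus)},
    ).drop_empty_motus()
    return cleaned, report


def exclusion_percentages(report: pd.DataFrame, n_input_motus: int) -> dict[str, float]:
    """Percentage of the input MOTUs removed per reason (unrounded)."""
    out = {}
    for reason, sub in report.groupby("reason"):
        out[reason] = 100.0 * len(sub) / n_input_motus
    return out


def run_table_pipeline(
    table: MotuTable,
    taxonomy: dict[str, TaxonRecord],
    blank_sample_ids=(),
    min_reads: int = 5,
    relative_threshold: float = 1e-4,
    min_similarity: float = 40.0,
    exclusion_taxa: dict[str, tuple[str, ...]] | None = None,
) -> tuple[MotuTable, pd.DataFrame, dict]:
    """Table-level filter chain for pre-clustered MOTU tables.

    Applies the global minimum-count rule, the per-sample relative
    threshold, and non-target exclusion, in that order. Returns
    (cleaned table, exclusion report, attrition log).
    """
    log = {"input_motus": len(table.motu_ids), "input_reads": int(table.counts.to_numpy().sum())}
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_reads].index
    counts = table.counts[keep]
    log["after_min_reads_motus"] = len(keep)
    counts = within_sample_relative_filter(counts, relative_threshold)
    stage = MotuTable(
        counts=counts,
        centroids={m: s for m, s in table.centroids.items() if m in set(keep)},
    ).drop_empty_motus()
    log["after_relative_filter_motus"] = len(stage.motu_ids)
    cleaned, report = exclude_nontarget(
        stage,
        taxonomy,
        blank_sample_ids=blank_sample_ids,
        min_similarity=min_similarity,
        exclusion_taxa=exclusion_taxa,
    )
    log["excluded_motus"] = len(report)
    log["output_motus"] = len(cleaned.motu_ids)
    log["output_reads"] = int(cleaned.counts.to_numpy().sum())
    return cleaned, report, log
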