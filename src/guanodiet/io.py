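"""Readers and writers for the on-disk formats.

All tabular artifacts are TSV: UTF-8, Unix newlines, decimal point,
floats at 10 significant digits. MOTU tables have samples as rows (first
column ``sample_id``) and MOTU ids as the remaining header fields.
FASTQ input is gzip-transparent.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .read_pipeline import DEFAULT_EXCLUSION_TAXA, MotuTable, SequenceRead, TaxonRecord

__all__ = [
    "read_motu_table",
    "write_motu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_matrix",
    "write_matrix",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "load_exclusion_taxa",
    "write_json",
]

_FLOAT_FMT = "%.10g"

TAXONOMY_COLUMNS = ["motu_id", "class", "order", "family", "genus", "species", "similarity"]
METADATA_COLUMNS = ["sample_id", "colony", "date_index", "season", "regime", "pellet_count"]


class FormatError(ValueError):
    """Malformed input file; message carries the offending location."""


def read_motu_table(path) -> MotuTable:
    """Read a samples x MOTUs integer TSV, validating every cell."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    motus = list(df.columns[1:])
    if len(set(motus)) != len(motus):
        raise FormatError(f"{path}: duplicate MOTU ids in header")
    df = df.set_index("sample_id")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell at row {i + 2}, column {col!r}: {raw!r}"
                ) from None
            if v < 0:
                raise FormatError(f"{path}: negative count at row {i + 2}, column {col!r}")
            values[i, j] = v
    counts = pd.DataFrame(values, index=df.index, columns=df.columns)
    counts.index.name = "sample_id"
    return MotuTable(counts=counts)


def write_motu_table(table: MotuTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> dict[str, TaxonRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {missing}")
    records = {}
    for i, row in df.iterrows():
        motu = row["motu_id"]
        if motu in records:
            raise FormatError(f"{path}: duplicate motu_id {motu!r} at row {i + 2}")
        try:
            sim = float(row["similarity"]) if row["similarity"] else 0.0
        except ValueError:
            raise FormatError(f"{path}: bad similarity at row {i + 2}") from None
        records[motu] = TaxonRecord(
            motu_id=motu,
            class_=row["class"],
            order=row["order"],
            family=row["family"],
            genus=row["genus"],
            species=row["species"],
            match_similarity=sim,
            excluded_reason=row.get("excluded_reason", "none") or "none",
        )
    return records


def write_taxonomy(records: dict[str, TaxonRecord], path) -> None:
    rows = [
        {
            "motu_id": r.motu_id,
            "class": r.class_,
            "order": r.order,
            "family": r.family,
            "genus": r.genus,
            "species": r.species,
            "similarity": _FLOAT_FMT % r.match_similarity,
            "excluded_reason": r.excluded_reason,
        }
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path, season_of_date=None) -> pd.DataFrame:
    """Sample metadata table, optionally validated against a season map."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    df["date_index"] = df["date_index"].replace("", "0").astype(int)
    df["pellet_count"] = df["pellet_count"].replace("", "0").astype(int)
    meta = df.set_index("sample_id")
    if season_of_date is not None:
        for sid, row in meta.iterrows():
            if row["regime"] == "blank":
                continue
            expected = season_of_date[row["date_index"] - 1]
            if row["season"] != expected:
                raise FormatError(
                    f"{path}: sample {sid}: season {row['season']!r} inconsistent "
                    f"with date {row['date_index']} (expected {expected!r})"
                )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def check_taxonomy_coverage(table: MotuTable, taxonomy: dict[str, TaxonRecord]) -> list[str]:
    """MOTUs in the table with no taxonomy record (warning list)."""
    return [m for m in table.motu_ids if m not in taxonomy]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[SequenceRead]:
    with _open_maybe_gzip(path) as fh:
        return [
            SequenceRead(
                id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads, path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{quals}\n")


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def load_exclusion_taxa(path=None) -> dict[str, tuple[str, ...]]:
    """Exclusion-taxa config (YAML mapping category -> taxon list)."""
    if path is None:
        return {k: tuple(v) for k, v in DEFAULT_EXCLUSION_TAXA.items()}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(DEFAULT_EXCLUSION_TAXA)
    unknown = set(raw) - allowed
    if unknown:
        raise FormatError(f"{path}: unknown exclusion categories {sorted(unknown)}")
    return {k: tuple(raw.get(k, ())) for k in allowed}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
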