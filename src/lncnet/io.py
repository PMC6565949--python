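"""Readers and writers for the pipeline's on-disk formats.

Formats handled here:

* counts TSV — ``transcript_id`` column followed by one integer column per
  sample; the sample→group map travels in the manifest YAML.
* transcript annotation — a BED-like TSV (0-based, half-open) and a GTF twin
  (1-based, closed).  Both carry the same per-transcript fields: biotype,
  strand, exonic length, exon count and the three coding-potential verdicts
  (CPC-like, CNCI-like, Pfam-like; ``True`` = predicted coding).
* GMT gene-set files (tab-separated: name, description, member ids...).
* plain one-id-per-line gene lists.
* run manifests as YAML.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import yaml

ANNOTATION_COLUMNS = [
    "transcript_id",
    "biotype",
    "chrom",
    "start",
    "end",
    "strand",
    "exonic_length",
    "exon_count",
    "flag_cpc",
    "flag_cnci",
    "flag_pfam",
]

FLAG_COLUMNS = ["flag_cpc", "flag_cnci", "flag_pfam"]


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a transcript × sample integer count matrix as TSV."""
    out = counts.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a counts TSV; validates non-negative integer values."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    if df.empty:
        raise ValueError(f"empty count matrix in {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    if not (df.values == df.values.astype(int)).all():
        raise ValueError(f"non-integer counts in {path}")
    return df.astype(int)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the BED-like annotation TSV (coordinates 0-based, half-open)."""
    annotation.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns: {sorted(missing)}")
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    _validate_annotation(df, path)
    return df


def _validate_annotation(df: pd.DataFrame, source) -> None:
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "transcript_id"].iloc[0]
        raise ValueError(f"{source}: end <= start for transcript {bad}")
    if (df["exonic_length"] < 1).any() or (df["exon_count"] < 1).any():
        raise ValueError(f"{source}: exonic_length and exon_count must be >= 1")


def write_gtf(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write transcript-feature GTF lines (1-based, closed intervals).

    Attributes carry the non-positional fields so the file round-trips
    losslessly through :func:`read_gtf`.
    """
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = (
                f'transcript_id "{row.transcript_id}"; '
                f'biotype "{row.biotype}"; '
                f"exonic_length {row.exonic_length}; "
                f"exon_count {row.exon_count}; "
                f'coding_flags "{int(row.flag_cpc)}{int(row.flag_cnci)}{int(row.flag_pfam)}";'
            )
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        "lncnet",
                        "transcript",
                        str(row.start + 1),  # 0-based half-open -> 1-based closed
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gtf(path: str | os.PathLike) -> pd.DataFrame:
    """Parse transcript-feature GTF lines back into the annotation frame.

    Coordinates are converted to the in-memory 0-based, half-open convention.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line: {line!r}")
            chrom, _, feature, start1, end1, _, strand, _, attr_str = fields
            if feature != "transcript":
                continue
            attrs = _parse_gtf_attributes(attr_str)
            flags = attrs["coding_flags"]
            records.append(
                {
                    "transcript_id": attrs["transcript_id"],
                    "biotype": attrs["biotype"],
                    "chrom": chrom,
                    "start": int(start1) - 1,  # 1-based closed -> 0-based half-open
                    "end": int(end1),
                    "strand": strand,
                    "exonic_length": int(attrs["exonic_length"]),
                    "exon_count": int(attrs["exon_count"]),
                    "flag_cpc": flags[0] == "1",
                    "flag_cnci": flags[1] == "1",
                    "flag_pfam": flags[2] == "1",
                }
            )
    df = pd.DataFrame.from_records(records, columns=ANNOTATION_COLUMNS)
    _validate_annotation(df, path)
    return df


def _parse_gtf_attributes(attr_str: str) -> dict:
    attrs = {}
    for chunk in attr_str.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: member ids}``.

    Column 2 (description) is discarded.  Duplicate set names are an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, >=1 id")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """Read a one-id-per-line gene list (blank lines and '#' comments skipped)."""
    with open(path) as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        }


def write_manifest(manifest: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
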