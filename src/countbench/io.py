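"""Readers and writers for counts, annotation, design tables and results.

Counts come in as TSV (genes x samples with header) or Matrix Market triplets
with sidecar row/column label files.  Annotation comes in as BED (0-based
half-open) or GFF3 (1-based closed, converted on read).  All result tables go
out as TSV with a fixed column order so regression tests can diff them.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    GENIC,
    PROTEIN_CODING,
    CountMatrix,
    FeatureTable,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation_bed",
    "read_design",
    "write_design",
    "write_table",
    "read_table",
    "write_manifest",
]


def read_count_matrix(path, format: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count matrix.

    ``format='tsv'``: gene rows x sample columns, first column gene ids.
    ``format='mtx'``: Matrix Market file; row labels in ``<stem>.rows.txt``
    and column labels in ``<stem>.cols.txt`` next to it.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValidationError(f"malformed count TSV {path}: {exc}") from exc
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        rows = Path(f"{stem}.rows.txt").read_text().split()
        cols = Path(f"{stem}.cols.txt").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValidationError(f"unknown count format {format!r}")
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_annotation(
    path,
    format: str = "gff3",
    read_length: int = 76,
    region_attribute: str = "region_class",
    coding_attribute: str = "coding_class",
) -> FeatureTable:
    """Read feature annotation from GFF3 or BED.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention, so a GFF3 feature 101..300 and a BED line
    ``chrom 100 300`` describe the same 200 bp interval.  Region and coding
    classes are taken from GFF3 attributes (defaults above) or, for BED, from
    optional 7th/8th columns; anything unannotated is genic/protein_coding.
    """
    path = Path(path)
    records = []
    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}"
                    )
                chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
                attr = _parse_gff3_attributes(attrs)
                fid = attr.get("ID", attr.get("Name", f"feature_{lineno}"))
                records.append(
                    {
                        "feature_id": fid,
                        "chrom": chrom,
                        "start": int(start) - 1,  # 1-based closed -> 0-based half-open
                        "end": int(end),
                        "strand": strand if strand in "+-." else strand,
                        "region_class": attr.get(region_attribute, GENIC),
                        "coding_class": attr.get(coding_attribute, PROTEIN_CODING),
                    }
                )
    elif format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValidationError(
                        f"{path}:{lineno}: BED needs at least 4 columns"
                    )
                chrom, start, end, name = parts[:4]
                strand = parts[5] if len(parts) > 5 else "."
                region = parts[6] if len(parts) > 6 else GENIC
                coding = parts[7] if len(parts) > 7 else PROTEIN_CODING
                records.append(
                    {
                        "feature_id": name,
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "strand": strand,
                        "region_class": region,
                        "coding_class": coding,
                    }
                )
    else:
        raise ValidationError(f"unknown annotation format {format!r}")
    if not records:
        raise ValidationError(f"no features parsed from {path}")
    df = pd.DataFrame.from_records(records).set_index("feature_id")
    return FeatureTable(df, read_length=read_length)


def write_annotation_bed(ft: FeatureTable, path) -> None:
    t = ft.table
    with open(path, "w") as fh:
        for fid, row in t.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{fid}\t0\t"
                f"{row['strand']}\t{row['region_class']}\t{row['coding_class']}\n"
            )


def write_annotation_gff3(ft: FeatureTable, path) -> None:
    t = ft.table
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for fid, row in t.iterrows():
            ftype = "gene" if row["region_class"] == GENIC else "region"
            attrs = (
                f"ID={fid};region_class={row['region_class']};"
                f"coding_class={row['coding_class']}"
            )
            fh.write(
                f"{row['chrom']}\tcountbench\t{ftype}\t{row['start'] + 1}\t"
                f"{row['end']}\t.\t{row['strand']}\t.\t{attrs}\n"
            )


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleDesign(df)


def write_design(sd: SampleDesign, path) -> None:
    sd.table.to_csv(path, sep="\t", index_label="sample_id")


def write_table(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """TSV with full-precision floats (repr-level round-trip)."""
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_manifest(path, config: dict, extra: dict | None = None) -> None:
    manifest = {"config": config}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
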