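"""Readers, writers and count-level preprocessing.

Every external table the pipeline touches is tab-separated UTF-8 text with
``#`` comment lines ignored.  Genomic coordinates are held internally as
1-based closed intervals; BED input/output is converted at the boundary
(0-based half-open on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "cpm_normalize",
    "filter_expressed_genes",
    "read_sample_sheet",
    "read_triad_table",
    "read_deg_table",
    "read_gene_annotation",
    "write_gene_annotation",
]

VALID_UNITS = ("counts", "CPM", "TPM", "log2")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    unit : str
        One of ``counts``, ``CPM``, ``TPM`` or ``log2``.  Units other than
        ``log2`` must be non-negative.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicated sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(f"non-finite value at gene {idx[g]!r}, sample {cols[s]!r}")
        if self.unit != "log2" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(f"negative value at gene {idx[g]!r}, sample {cols[s]!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header sample ids)."""
    # scan the header ourselves: pandas silently mangles duplicate columns
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")
            break
        else:
            raise ValueError(f"{path}: empty file")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicated sample id: {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.columns = samples
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from None
    values.index = values.index.astype(str)
    return ExpressionMatrix(values, unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalisation: each column scaled to sum 1e6."""
    if counts.unit != "counts":
        raise ValueError(f"cpm_normalize expects counts, got unit {counts.unit!r}")
    libsize = counts.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return ExpressionMatrix(counts.values / libsize * 1e6, "CPM")


def filter_expressed_genes(cpm: ExpressionMatrix, threshold: float = 1.0,
                           min_samples: int = 1) -> pd.Index:
    """Genes with CPM >= threshold in at least ``min_samples`` samples.

    The boundary is inclusive: a gene at exactly the threshold in one
    sample is retained.
    """
    if cpm.unit != "CPM":
        raise ValueError(f"filter_expressed_genes expects CPM, got unit {cpm.unit!r}")
    keep = (cpm.values >= threshold).sum(axis=1) >= min_samples
    return cpm.gene_ids[keep]


# ---------------------------------------------------------------------------
# sample sheet / triads / DEG tables


def read_sample_sheet(path, stage_order: list[str] | None = None) -> pd.DataFrame:
    """Read the sample sheet (sample_id, genotype, stage, replicate).

    Stages become an ordered categorical; the order is ``stage_order`` if
    given, else first appearance in the file (sample sheets are written in
    chronological stage order).
    """
    df = _read_tsv(path)
    required = ["sample_id", "genotype", "stage", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup!r}")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] <= 0).any():
        raise ValueError("replicate numbers must be positive")
    order = stage_order if stage_order is not None else list(dict.fromkeys(df["stage"]))
    unknown = set(df["stage"]) - set(order)
    if unknown:
        raise ValueError(f"stages not in stage_order: {sorted(unknown)}")
    df["stage"] = pd.Categorical(df["stage"], categories=order, ordered=True)
    return df.reset_index(drop=True)


def read_triad_table(path) -> pd.DataFrame:
    """Read the 1:1:1 A/B/D triad correspondence table."""
    df = _read_tsv(path)
    required = ["triad_id", "gene_A", "gene_B", "gene_D"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"triad table missing columns: {missing}")
    if df["triad_id"].duplicated().any():
        dup = df.loc[df["triad_id"].duplicated(), "triad_id"].iloc[0]
        raise ValueError(f"duplicated triad id: {dup!r}")
    genes = pd.concat([df["gene_A"], df["gene_B"], df["gene_D"]])
    if genes.isna().any() or (genes.astype(str).str.strip() == "").any():
        raise ValueError("triad table has an empty gene slot")
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} appears in more than one triad slot")
    return df.reset_index(drop=True)


def read_deg_table(path) -> pd.DataFrame:
    """Read a DEG table (gene_id, log2fc, padj, contrast); adds ``direction``."""
    df = _read_tsv(path)
    required = ["gene_id", "log2fc", "padj", "contrast"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    df["log2fc"] = df["log2fc"].astype(float)
    df["padj"] = df["padj"].astype(float)
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    if df.duplicated(subset=["gene_id", "contrast"]).any():
        bad = df[df.duplicated(subset=["gene_id", "contrast"])].iloc[0]
        raise ValueError(
            f"gene {bad['gene_id']!r} appears twice in contrast {bad['contrast']!r}")
    df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / BED)

_ANN_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _finalize_annotation(records: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=_ANN_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id in annotation: {dup!r}")
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValueError(f"end < start for gene {bad['gene_id']!r}")
    if (df["start"] <= 0).any():
        bad = df[df["start"] <= 0].iloc[0]
        raise ValueError(f"non-positive coordinate for gene {bad['gene_id']!r}")
    return df


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path, dialect: str = "gff3") -> pd.DataFrame:
    """Read gene coordinates from GFF3 or BED into 1-based closed intervals.

    GFF3 is 1-based closed (stored unchanged, ``gene`` features only);
    BED is 0-based half-open (start shifted by +1).
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if gene_id is None:
                        raise ValueError("gene feature without ID attribute")
                    gene_id = gene_id.removeprefix("gene:")
                    records.append((gene_id, fields[0], int(fields[3]),
                                    int(fields[4]), fields[6]))
                else:
                    if len(fields) < 4:
                        raise ValueError("expected at least 4 BED fields")
                    strand = fields[5] if len(fields) >= 6 else "."
                    records.append((fields[3], fields[0], int(fields[1]) + 1,
                                    int(fields[2]), strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed {dialect} line ({exc})") from None
    return _finalize_annotation(records)


def write_gene_annotation(annotation: pd.DataFrame, path, dialect: str = "gff3") -> None:
    """Write annotation back out; BED output is 0-based half-open."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for row in annotation.itertuples(index=False):
                fh.write(f"{row.chrom}\ttriadscan\tgene\t{row.start}\t{row.end}\t.\t"
                         f"{row.strand}\t.\tID={row.gene_id}\n")
        elif dialect == "bed":
            for row in annotation.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t"
                         f"{row.strand}\n")
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")
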