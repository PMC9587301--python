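"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV (CSV for the probe manifest) with deterministic float
formatting so identical runs produce byte-identical files. Annotation is
written both as GTF (1-based, inclusive) and BED6 (0-based, half-open);
both readers reconstruct the same annotation table, TSS included.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"

__all__ = [
    "write_tsv", "read_tsv", "write_matrix", "read_matrix",
    "write_manifest", "read_manifest", "write_gtf", "read_gtf",
    "write_bed6", "read_bed6",
]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT,
              lineterminator="\n")


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Feature-by-sample matrix with the feature id as first column."""
    write_tsv(df, path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path)
    for col in ("snp_overlap", "context_nonCpG", "sex_chrom"):
        man[col] = man[col].astype(bool)
    return man


def write_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    """One gene feature per row; 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for r in annotation.itertuples(index=False):
            attrs = f'gene_id "{r.gene_id}";'
            fh.write("\t".join([
                r.chrom, "methlink", "gene", str(r.start + 1), str(r.end),
                ".", r.strand, ".", attrs]) + "\n")


def read_gtf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            gene_id = f[8].split('gene_id "')[1].split('"')[0]
            start = int(f[3]) - 1
            end = int(f[4])
            strand = f[6]
            rows.append((gene_id, f[0], start, end, strand,
                         start if strand == "+" else end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


def write_bed6(annotation: pd.DataFrame, path: str | Path,
               score: int = 0) -> None:
    """0-based half-open BED6: chrom, start, end, name, score, strand."""
    with open(path, "w") as fh:
        for r in annotation.itertuples(index=False):
            fh.write("\t".join([r.chrom, str(r.start), str(r.end),
                                r.gene_id, str(score), r.strand]) + "\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = \
                line.rstrip("\n").split("\t")[:6]
            start, end = int(start), int(end)
            rows.append((name, chrom, start, end, strand,
                         start if strand == "+" else end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])
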