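"""Readers and writers for the plain-text genomic formats the pipeline uses.

All coordinates are 0-based half-open internally and in BED/bedGraph output.
Writers emit sorted, tab-delimited, newline-terminated files so identical
inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    """Write a BED6(+extra) file; missing BED columns are filled with '.'"""
    out = pd.DataFrame()
    out["chrom"] = df["chrom"]
    out["start"] = df["start"].astype(int)
    out["end"] = df["end"].astype(int)
    out["name"] = df["name"] if "name" in df else "."
    out["score"] = df["score"] if "score" in df else 0
    out["strand"] = df["strand"] if "strand" in df else "."
    for c in extra_cols or []:
        out[c] = df[c]
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = BED6_COLS + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def write_points_bed(df: pd.DataFrame, path) -> None:
    """Write 1-bp point features (e.g. fragment midpoints) as BED3."""
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["pos"].astype(int)})
    out["end"] = out["start"] + 1
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_points_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "pos"], comment="#")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    """Write (chrom, start, end, value) coverage intervals as bedGraph."""
    out = df[["chrom", "start", "end", "value"]].copy()
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"], comment="#")


def points_to_bedgraph(points: pd.DataFrame) -> pd.DataFrame:
    """Collapse 1-bp point reads into a bedGraph-style coverage table."""
    g = (points.groupby(["chrom", "pos"]).size()
         .rename("value").reset_index())
    g["start"] = g["pos"].astype(int)
    g["end"] = g["start"] + 1
    return g[["chrom", "start", "end", "value"]]


def bedgraph_to_points(track: pd.DataFrame) -> pd.DataFrame:
    """Expand a 1-bp bedGraph track back into one row per read."""
    reps = track["value"].round().astype(int).clip(lower=0)
    return pd.DataFrame({
        "chrom": track["chrom"].repeat(reps).to_numpy(),
        "pos": track["start"].repeat(reps).to_numpy(),
    })


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genes(path) -> pd.DataFrame:
    """Gene models as TSV: gene, chrom, strand, tss, tes."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df
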