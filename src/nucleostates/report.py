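"""Reporting statistics: DE/ATAC threshold filters and overlap arithmetic."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def filter_de(de: pd.DataFrame) -> set[str]:
    """Significant genes under the strict |log2FC| > 1 and p < 0.05 rule.

    Malformed rows (non-finite log2FC, p outside [0, 1]) are dropped with
    their row numbers logged.
    """
    required = {"gene", "log2fc", "p"}
    if missing := required - set(de.columns):
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    lfc = pd.to_numeric(de["log2fc"], errors="coerce")
    p = pd.to_numeric(de["p"], errors="coerce")
    bad = ~np.isfinite(lfc) | ~np.isfinite(p) | (p < 0) | (p > 1)
    if bad.any():
        log.warning("rejecting malformed DE rows: %s",
                    list(de.index[bad]))
    ok = ~bad & (lfc.abs() > 1.0) & (p < 0.05)
    return set(de.loc[ok, "gene"])


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    intersection: int
    percentage: float  # 100 * |A & B| / |A|, half-up to 1 decimal


def overlap_percentage(a, b) -> OverlapReport:
    """Overlap of set A with set B as a percentage of A (half-up, 1 dp)."""
    a, b = set(a), set(b)
    if not a:
        raise ValueError("set A is empty")
    inter = len(a & b)
    pct = float(Decimal(100 * inter / len(a)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))
    return OverlapReport(len(a), len(b), inter, pct)


def atac_open_fraction(sites: pd.DataFrame, peaks: pd.DataFrame) -> float:
    """Fraction of sites overlapping >= 1 ATAC peak (1 bp suffices).

    Intervals are 0-based half-open; a site [100, 200) and a peak [199, 300)
    overlap.
    """
    if sites.empty:
        return 0.0
    if peaks.empty:
        return 0.0
    hits = np.zeros(len(sites), bool)
    for chrom, psub in peaks.groupby("chrom", sort=True):
        smask = (sites["chrom"] == chrom).to_numpy()
        if not smask.any():
            continue
        starts = psub["start"].to_numpy()
        ends = psub["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        # merge overlapping peaks so a sorted-interval test suffices
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        m_starts = np.asarray(m_starts)
        m_ends = np.asarray(m_ends)
        s_start = sites.loc[smask, "start"].to_numpy()
        s_end = sites.loc[smask, "end"].to_numpy()
        # peak with the greatest start < site end; overlaps iff its end > start
        j = np.searchsorted(m_starts, s_end, "left") - 1
        valid = j >= 0
        ov = np.zeros(valid.shape, bool)
        ov[valid] = m_ends[j[valid]] > s_start[valid]
        hits[np.nonzero(smask)[0]] = ov
    return float(hits.mean())


def atac_differential_filter(peaks: pd.DataFrame) -> tuple[pd.DataFrame,
                                                           pd.DataFrame]:
    """Hyper-/hypo-accessible peaks: |log2FC| > 1 and adjusted p < 0.01."""
    lfc = pd.to_numeric(peaks["log2fc"], errors="coerce")
    padj = pd.to_numeric(peaks["padj"], errors="coerce")
    hyper = peaks[(lfc > 1.0) & (padj < 0.01)]
    hypo = peaks[(lfc < -1.0) & (padj < 0.01)]
    return hyper, hypo
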