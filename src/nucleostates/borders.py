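"""Paired 1-bp binding-border analysis against the nucleosome map.

Border pairs (left/right 1-bp boundaries of a protein footprint) are reduced
to their midpoint, assigned to the nearest dyad within 100 bp, and summarised
as gap distributions, signed dyad-offset profiles and edge-binding fractions
(the edge window is 50-60 bp from the dyad).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ASSIGN_RADIUS = 100
EDGE_WINDOW = (50, 60)


def pair_gap_distribution(pairs: pd.DataFrame,
                          max_gap: int = 100) -> tuple[pd.Series, int]:
    """1-bp histogram of border gaps <= max_gap and the modal gap (ties low)."""
    if pairs.empty:
        raise ValueError("no border pairs")
    gaps = (pairs["right"] - pairs["left"]).to_numpy()
    if (gaps < 0).any():
        raise ValueError("right border precedes left border")
    gaps = gaps[gaps <= max_gap]
    counts = np.bincount(gaps, minlength=max_gap + 1)
    hist = pd.Series(counts, index=np.arange(max_gap + 1), name="count")
    return hist, int(np.argmax(counts))


def assign_to_nucleosomes(pairs: pd.DataFrame, nucleosomes: pd.DataFrame,
                          max_offset: int = ASSIGN_RADIUS) -> pd.DataFrame:
    """Assign each pair midpoint to the nearest dyad within max_offset bp.

    The returned table has one row per pair: assigned nucleosome index (-1 if
    none), signed offset (midpoint - dyad), inherited state and an edge flag
    (|offset| within the 50-60 bp window).
    """
    mid = ((pairs["left"] + pairs["right"]) // 2).to_numpy()
    nuc_idx = np.full(len(pairs), -1, dtype=np.int64)
    offset = np.full(len(pairs), np.nan)
    state = np.full(len(pairs), None, dtype=object)

    for chrom, nsub in nucleosomes.groupby("chrom", sort=True):
        pmask = (pairs["chrom"] == chrom).to_numpy()
        if not pmask.any():
            continue
        dyads = nsub["dyad"].to_numpy()
        order = np.argsort(dyads, kind="mergesort")
        dyads = dyads[order]
        src_idx = nsub.index.to_numpy()[order]
        m = mid[pmask]
        right = np.searchsorted(dyads, m, "left")
        left = np.clip(right - 1, 0, None)
        right = np.clip(right, None, dyads.size - 1)
        dl = np.abs(m - dyads[left])
        dr = np.abs(m - dyads[right])
        pick = np.where(dl <= dr, left, right)
        off = m - dyads[pick]
        ok = np.abs(off) <= max_offset
        rows = np.nonzero(pmask)[0]
        nuc_idx[rows[ok]] = src_idx[pick[ok]]
        offset[rows[ok]] = off[ok]
        if "state" in nsub.columns:
            state[rows[ok]] = nsub["state"].to_numpy()[order][pick[ok]]

    lo, hi = EDGE_WINDOW
    edge = np.where(np.isnan(offset), False,
                    (np.abs(offset) >= lo) & (np.abs(offset) <= hi))
    out = pairs[["chrom", "left", "right"]].copy()
    if "pair_id" in pairs.columns:
        out["pair_id"] = pairs["pair_id"]
    out["nuc_idx"] = nuc_idx
    out["offset"] = offset
    out["state"] = state
    out["edge"] = edge.astype(bool)
    return out


def edge_statistics(assignments: pd.DataFrame,
                    states: list[str] | None = None,
                    window: int = ASSIGN_RADIUS) -> dict:
    """Edge-binding fraction and signed offset profile for assigned pairs."""
    sub = assignments[assignments["nuc_idx"] >= 0]
    if states is not None:
        sub = sub[sub["state"].isin(states)]
    if sub.empty:
        raise ValueError("no assigned pairs in the requested states")
    offs = sub["offset"].to_numpy().astype(int)
    hist = np.bincount(offs + window, minlength=2 * window + 1)
    profile = pd.Series(hist, index=np.arange(-window, window + 1),
                        name="count")
    n_left = int((offs < 0).sum())
    n_right = int((offs > 0).sum())
    return {
        "n": len(sub),
        "edge_fraction": float(sub["edge"].mean()),
        "offset_profile": profile,
        "symmetry_ratio": (n_left / n_right if n_right else np.inf),
    }


def on_nucleosome_fraction(assignments: pd.DataFrame) -> float:
    """Fraction of all pairs assigned to a nucleosome."""
    if assignments.empty:
        raise ValueError("no border pairs")
    return float((assignments["nuc_idx"] >= 0).mean())


def border_to_gene(pairs: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Assign each pair midpoint to one gene by the body > promoter >
    proximal > distal priority order (none if outside all windows)."""
    from .switching import associate_genes
    spans = pd.DataFrame({
        "chrom": pairs["chrom"],
        "start": pairs["left"],
        "end": pairs["right"],
    })
    out = associate_genes(spans, genes)
    out.name = "gene"
    return out
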