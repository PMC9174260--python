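"""Condition comparison: region matching, transition tables, RAS flags.

Regions (state-labelled nucleosome groups) from two conditions are matched by
reciprocal span overlap; an A-region whose span holds no condition-B
nucleosome becomes nucleosome-free (NFR).  The matched table yields the
state-transition counts/percentages (Sankey input), per-state switched
fractions and DHT/Veh state-count ratios, and per-region flags for the two
relatively-accessible-state switches: S4 -> {S2,S3,S7,NFR} (RAS1) and
S3 -> {S2,S6,NFR} (RAS2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEST_STATES, NFR, RAS1, RAS2


def match_regions(groups_a: pd.DataFrame, groups_b: pd.DataFrame,
                  nucleosomes_b: pd.DataFrame | None = None,
                  min_overlap: float = 0.5) -> pd.DataFrame:
    """Match condition-A groups to condition-B groups by span overlap.

    Overlap is measured against the shorter span (containment-aware), so a
    state switch that shrinks or grows an array in place still matches; the
    threshold is configurable.  Each B group is used at most once (greedy by
    overlap, ties to the leftmost A span).  A groups whose span contains no
    B nucleosome get ``state_b = NFR``; unmatched A groups with B signal are
    labelled None and excluded from transition counting.
    """
    required = {"chrom", "start", "end", "state"}
    for name, df in (("A", groups_a), ("B", groups_b)):
        if missing := required - set(df.columns):
            raise ValueError(f"groups {name} missing columns {missing}")

    a = groups_a.reset_index(drop=True)
    b = groups_b.reset_index(drop=True)
    cand = []
    for chrom, asub in a.groupby("chrom", sort=True):
        bsub = b[b["chrom"] == chrom]
        if bsub.empty:
            continue
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bs, be = bs[order], be[order]
        bidx = bsub.index.to_numpy()[order]
        for ai, astart, aend in zip(asub.index, asub["start"], asub["end"]):
            j0 = np.searchsorted(be, astart, "right")
            j1 = np.searchsorted(bs, aend, "left")
            for j in range(j0, j1):
                ov = min(aend, be[j]) - max(astart, bs[j])
                if ov <= 0:
                    continue
                shorter = min(aend - astart, be[j] - bs[j])
                containment = ov / shorter if shorter > 0 else 0.0
                if containment >= min_overlap:
                    frac_a = ov / (aend - astart) if aend > astart else 0.0
                    cand.append((containment, astart, ai, bidx[j], frac_a))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    a_match: dict[int, tuple[int, float]] = {}
    b_used: set[int] = set()
    for containment, _, ai, bj, frac_a in cand:
        if ai in a_match or bj in b_used:
            continue
        a_match[ai] = (bj, frac_a)
        b_used.add(bj)

    # NFR test: any B nucleosome dyad inside the A span?
    has_b_signal = np.zeros(len(a), bool)
    source = nucleosomes_b if nucleosomes_b is not None else b.rename(
        columns={"start": "start", "end": "end"})
    for chrom, asub in a.groupby("chrom", sort=True):
        if nucleosomes_b is not None:
            pts = np.sort(source.loc[source["chrom"] == chrom,
                                     "dyad"].to_numpy())
            lo = np.searchsorted(pts, asub["start"].to_numpy(), "left")
            hi = np.searchsorted(pts, asub["end"].to_numpy(), "left")
            has_b_signal[asub.index] = hi > lo
        else:
            bsub = source[source["chrom"] == chrom]
            for ai, astart, aend in zip(asub.index, asub["start"],
                                        asub["end"]):
                has_b_signal[ai] = bool(((bsub["start"] < aend)
                                         & (bsub["end"] > astart)).any())

    rows = []
    for ai in range(len(a)):
        if ai in a_match:
            bj, frac = a_match[ai]
            state_b = b.loc[bj, "state"]
        elif not has_b_signal[ai]:
            bj, frac, state_b = -1, 0.0, NFR
        else:
            bj, frac, state_b = -1, 0.0, None
        rows.append({
            "region_id": a.loc[ai, "group_id"] if "group_id" in a else ai,
            "chrom": a.loc[ai, "chrom"],
            "start": a.loc[ai, "start"],
            "end": a.loc[ai, "end"],
            "state_a": a.loc[ai, "state"],
            "state_b": state_b,
            "b_group": bj,
            "overlap": frac,
        })
    return pd.DataFrame(rows)


@dataclass
class TransitionTable:
    counts: pd.DataFrame        # state_a x state_b counts
    row_percent: pd.DataFrame   # row-normalised percentages
    switched: pd.Series         # % of each A state assigned a different state
    state_ratio: pd.Series      # 100 * (#state in B) / (#state in A)

    @property
    def n_regions(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_sankey(self) -> list[dict]:
        links = []
        for sa in self.counts.index:
            for sb in self.counts.columns:
                v = int(self.counts.loc[sa, sb])
                if v:
                    links.append({"source": f"Veh:{sa}",
                                  "target": f"DHT:{sb}", "value": v})
        return links


def transition_table(matched: pd.DataFrame) -> TransitionTable:
    """Count and normalise state transitions over matched regions."""
    ok = matched[matched["state_b"].notna()]
    if ok.empty:
        raise ValueError("no matched regions with assigned states")
    states = [s for s in DEST_STATES]
    counts = pd.crosstab(ok["state_a"], ok["state_b"])
    counts = counts.reindex(index=states, columns=states, fill_value=0)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(row_tot, axis=0) * 100.0
    diag = pd.Series(np.diag(counts), index=states, dtype=float)
    switched = 100.0 * (1.0 - diag / row_tot.replace(0, np.nan))
    col_tot = counts.sum(axis=0)
    ratio = 100.0 * col_tot / row_tot.replace(0, np.nan)
    return TransitionTable(counts, pct, switched, ratio)


def flag_switches(matched: pd.DataFrame) -> pd.Series:
    """Per-region flag: 'S4->RAS1', 'S3->RAS2' or 'other' (exclusive)."""
    sa = matched["state_a"].to_numpy(dtype=object)
    sb = matched["state_b"].to_numpy(dtype=object)
    out = np.full(len(matched), "other", dtype=object)
    out[(sa == "S4") & np.isin(sb, list(RAS1))] = "S4->RAS1"
    out[(sa == "S3") & np.isin(sb, list(RAS2))] = "S3->RAS2"
    return pd.Series(out, index=matched.index, name="ras_flag")


def associate_genes(regions: pd.DataFrame, genes: pd.DataFrame,
                    promoter: int = 1_000, proximal: int = 5_000,
                    distal: int = 50_000) -> pd.Series:
    """Assign each region (by span midpoint) to at most one gene.

    Priority: gene body > promoter (1 kb upstream) > proximal (1-5 kb
    upstream) > distal (5-50 kb upstream) > none.  Within a priority tier the
    nearest TSS wins; exact ties break to the lexicographically smaller gene.
    """
    mids = ((regions["start"] + regions["end"]) // 2).to_numpy()
    chroms = regions["chrom"].to_numpy()
    assigned = np.full(len(regions), None, dtype=object)
    best = np.full((len(regions), 2), np.inf)  # (tier, distance)
    best_gene = np.full(len(regions), "", dtype=object)

    for gi, g in genes.iterrows():
        tss, tes = int(g["tss"]), int(g["tes"])
        lo, hi = min(tss, tes), max(tss, tes)
        on_chrom = chroms == g["chrom"]
        if not on_chrom.any():
            continue
        pos = mids
        upstream = (pos - tss) if g["strand"] == "-" else (tss - pos)
        dist = np.abs(pos - tss)
        tier = np.full(len(regions), np.inf)
        tier[(pos >= lo) & (pos < hi)] = 0                       # gene body
        in_prom = (upstream > 0) & (upstream <= promoter)
        tier = np.where((tier == np.inf) & in_prom, 1, tier)
        in_prox = (upstream > promoter) & (upstream <= proximal)
        tier = np.where((tier == np.inf) & in_prox, 2, tier)
        in_dist = (upstream > proximal) & (upstream <= distal)
        tier = np.where((tier == np.inf) & in_dist, 3, tier)
        cand = on_chrom & (tier < np.inf)
        better = cand & (
            (tier < best[:, 0])
            | ((tier == best[:, 0]) & (dist < best[:, 1]))
            | ((tier == best[:, 0]) & (dist == best[:, 1])
               & (best_gene > str(g["gene"]))))
        assigned[better] = g["gene"]
        best[better, 0] = tier[better]
        best[better, 1] = dist[better]
        best_gene[better] = str(g["gene"])
    return pd.Series(assigned, index=regions.index, name="gene")
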