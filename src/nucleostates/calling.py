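"""Nucleosome dyad calling from fragment midpoints, plus positioning QC.

The caller smooths the 1-bp midpoint count profile with a Gaussian kernel
(bandwidth ``w`` = 30 bp by default), takes local maxima as dyads, merges
maxima closer than 120 bp (keeping the higher peak) and bounds footprints by
the flanking density minima clipped to dyad +- 100 bp.  The peak area S is the
density integral over the footprint and the degree of positioning is the
fraction of footprint-scale midpoints concentrated within +-20 bp of the dyad
(midpoints in dyad +- 20 over midpoints in dyad +- 73).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

NUC_COLUMNS = ["chrom", "start", "end", "dyad", "score", "width", "dop"]


class NucleosomeCaller(BaseEstimator, TransformerMixin):
    """Gaussian-smoothing local-maximum dyad caller.

    Parameters
    ----------
    bandwidth : float, default 30
        Gaussian kernel sd in bp applied to the midpoint count profile.
    merge_distance : int, default 120
        Maxima closer than this are merged, keeping the higher peak.
    footprint_clip : int, default 100
        Footprint bounds never extend further than this from the dyad.
    """

    def __init__(self, bandwidth: float = 30.0, merge_distance: int = 120,
                 footprint_clip: int = 100):
        self.bandwidth = bandwidth
        self.merge_distance = merge_distance
        self.footprint_clip = footprint_clip

    def fit(self, X: pd.DataFrame, y=None) -> "NucleosomeCaller":
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.n_features_in_ = 2
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Call nucleosomes from a (chrom, pos) midpoint table."""
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        parts = []
        for chrom, sub in X.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"midpoints on {chrom} are not sorted")
            part = self._call_chrom(pos)
            part.insert(0, "chrom", chrom)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=NUC_COLUMNS)
        return pd.concat(parts, ignore_index=True)[NUC_COLUMNS]

    # -- internals --------------------------------------------------------
    def _call_chrom(self, pos: np.ndarray) -> pd.DataFrame:
        cols = NUC_COLUMNS[1:]
        if pos.size == 0:
            return pd.DataFrame(columns=cols)
        pad = int(4 * self.bandwidth) + 1
        lo = int(pos.min()) - pad
        hi = int(pos.max()) + pad
        counts = np.bincount(pos - lo, minlength=hi - lo + 1).astype(float)
        dens = gaussian_filter1d(counts, self.bandwidth, mode="constant")

        peaks = _local_maxima(dens)
        peaks = _merge_close(peaks, dens, self.merge_distance)
        if peaks.size == 0:
            return pd.DataFrame(columns=cols)

        rows = []
        for i, pk in enumerate(peaks):
            left_lim = peaks[i - 1] if i > 0 else 0
            right_lim = peaks[i + 1] if i < peaks.size - 1 else dens.size - 1
            lmin = left_lim + int(np.argmin(dens[left_lim:pk + 1]))
            rmin = pk + int(np.argmin(dens[pk:right_lim + 1]))
            start = max(lmin, pk - self.footprint_clip)
            end = min(rmin, pk + self.footprint_clip) + 1
            s = float(dens[start:end].sum())
            n73 = np.searchsorted(pos, pk + lo + 73, "right") - \
                np.searchsorted(pos, pk + lo - 73, "left")
            n20 = np.searchsorted(pos, pk + lo + 20, "right") - \
                np.searchsorted(pos, pk + lo - 20, "left")
            dop = n20 / n73 if n73 > 0 else 0.0
            rows.append((start + lo, end + lo, pk + lo, s, end - start, dop))
        return pd.DataFrame(rows, columns=cols)


def _local_maxima(dens: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their midpoint."""
    if dens.size < 3:
        return np.array([], dtype=int)
    rising = np.diff(dens) > 0
    falling = np.diff(dens) < 0
    # plateau-tolerant: a maximum is the midpoint of a run where the last
    # nonzero slope before it was rising and the next is falling
    slope = np.sign(np.diff(dens))
    idx = np.nonzero(slope)[0]
    peaks = []
    for a, b in zip(idx[:-1], idx[1:]):
        if slope[a] > 0 and slope[b] < 0:
            peaks.append((a + 1 + b) // 2)
    del rising, falling
    return np.asarray(peaks, dtype=int)


def _merge_close(peaks: np.ndarray, dens: np.ndarray,
                 min_sep: int) -> np.ndarray:
    """Greedily drop the lower of any peak pair closer than min_sep bp."""
    peaks = list(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        out = [peaks[0]]
        for pk in peaks[1:]:
            if pk - out[-1] < min_sep:
                if dens[pk] > dens[out[-1]]:
                    out[-1] = pk
                changed = True
            else:
                out.append(pk)
        peaks = out
    return np.asarray(peaks, dtype=int)


def call_dyads(midpoints: pd.DataFrame, bandwidth: float = 30.0,
               **kwargs) -> pd.DataFrame:
    """Functional wrapper around :class:`NucleosomeCaller`."""
    return NucleosomeCaller(bandwidth=bandwidth, **kwargs).fit(
        midpoints).transform(midpoints)


# ---------------------------------------------------------------------------
# spacing statistics
# ---------------------------------------------------------------------------

@dataclass
class SpacingStats:
    histogram: pd.Series  # 1-bp counts over [lo, hi]
    mode: int
    mean: float

    @property
    def lo(self) -> int:
        return int(self.histogram.index[0])

    @property
    def hi(self) -> int:
        return int(self.histogram.index[-1])


def spacing_stats(nucleosomes: pd.DataFrame, lo: int = 150,
                  hi: int = 350) -> SpacingStats:
    """Inter-dyad spacing histogram over [lo, hi] bp; mode ties break low."""
    diffs = []
    for _, sub in nucleosomes.groupby("chrom", sort=True):
        d = np.diff(np.sort(sub["dyad"].to_numpy()))
        diffs.append(d)
    diffs = np.concatenate(diffs) if diffs else np.array([])
    diffs = diffs[(diffs >= lo) & (diffs <= hi)]
    if diffs.size == 0:
        raise ValueError("no spacing defined: fewer than two nucleosomes "
                         "per chromosome within the spacing range")
    counts = np.bincount(diffs.astype(int) - lo, minlength=hi - lo + 1)
    hist = pd.Series(counts, index=np.arange(lo, hi + 1), name="count")
    mode = int(hist.index[int(np.argmax(counts))])  # argmax -> smallest tie
    return SpacingStats(hist, mode, float(diffs.mean()))


# ---------------------------------------------------------------------------
# genomic region scheme
# ---------------------------------------------------------------------------

@dataclass
class RegionScheme:
    """Strand-oriented windows around the TSS (bp, half-open).

    Promoter spans [TSS-1000, TSS+1000); Proximal and Distal are
    upstream-only: [1000, 5000) and [5000, 50000) bp upstream of the TSS.
    """

    promoter: int = 1_000
    proximal: int = 5_000
    distal: int = 50_000


def assign_region(positions, genes: pd.DataFrame,
                  scheme: RegionScheme | None = None) -> pd.DataFrame:
    """Label positions as Promoter/Proximal/Distal (nearest TSS wins).

    ``positions`` is a (chrom, pos) DataFrame or a list of (chrom, pos)
    tuples.  Returns a DataFrame with ``region`` (None outside all windows)
    and ``gene``.
    """
    scheme = scheme or RegionScheme()
    if not isinstance(positions, pd.DataFrame):
        positions = pd.DataFrame(positions, columns=["chrom", "pos"])
    n = len(positions)
    region = np.full(n, None, dtype=object)
    gene = np.full(n, None, dtype=object)
    best = np.full(n, np.inf)

    for chrom, gsub in genes.groupby("chrom", sort=True):
        pmask = (positions["chrom"] == chrom).to_numpy()
        if not pmask.any():
            continue
        pos = positions.loc[pmask, "pos"].to_numpy()
        ridx = np.nonzero(pmask)[0]
        for _, g in gsub.iterrows():
            tss = int(g["tss"])
            upstream = pos - tss if g["strand"] == "-" else tss - pos
            dist = np.abs(pos - tss)
            label = np.full(pos.size, None, dtype=object)
            label[(pos >= tss - scheme.promoter)
                  & (pos < tss + scheme.promoter)] = "Promoter"
            # upstream windows are half-open in coordinates: e.g. on + strand
            # Proximal is [TSS-5000, TSS-1000), i.e. upstream in (1000, 5000]
            prox = (upstream > scheme.promoter) & (upstream <= scheme.proximal)
            label[prox] = "Proximal"
            dis = (upstream > scheme.proximal) & (upstream <= scheme.distal)
            label[dis] = "Distal"
            hit = (label != None) & (dist < best[ridx])  # noqa: E711
            region[ridx[hit]] = label[hit]
            gene[ridx[hit]] = g["gene"]
            best[ridx[hit]] = dist[hit]
    return pd.DataFrame({"region": region, "gene": gene},
                        index=positions.index)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def replicate_correlation(track_a: pd.DataFrame, track_b: pd.DataFrame,
                          bin_size: int = 200) -> float:
    """Pearson r of binned read counts over bins with >= 1 read in either."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    chroms = sorted(set(track_a["chrom"]) | set(track_b["chrom"]))
    va, vb = [], []
    for chrom in chroms:
        pa = track_a.loc[track_a["chrom"] == chrom, "pos"].to_numpy() // bin_size
        pb = track_b.loc[track_b["chrom"] == chrom, "pos"].to_numpy() // bin_size
        nbins = int(max(pa.max(initial=-1), pb.max(initial=-1))) + 1
        va.append(np.bincount(pa, minlength=nbins))
        vb.append(np.bincount(pb, minlength=nbins))
    a = np.concatenate(va).astype(float)
    b = np.concatenate(vb).astype(float)
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance track: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def saturation_curve(midpoints: pd.DataFrame, fractions, seed: int = 0,
                     bandwidth: float = 30.0) -> pd.DataFrame:
    """Down-sampling saturation: #called dyads per retained read fraction."""
    fractions = list(fractions)
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(midpoints)
    rows = []
    for f in fractions:
        if f == 1.0:
            sub = midpoints
        else:
            take = rng.choice(n, size=int(round(f * n)), replace=False)
            sub = midpoints.iloc[np.sort(take)]
        rows.append((f, len(call_dyads(sub, bandwidth=bandwidth))))
    return pd.DataFrame(rows, columns=["fraction", "n_dyads"])


def dyad_centered_profile(dyads, midpoints: pd.DataFrame,
                          window: int = 600) -> np.ndarray:
    """Average midpoint count at each offset in [-window, window] per dyad."""
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(dyads, pd.DataFrame):
        dyads = dyads[["chrom", "dyad"]]
    else:
        dyads = pd.DataFrame(dyads, columns=["chrom", "dyad"])
    if len(dyads) == 0:
        raise ValueError("no dyads supplied")
    profile = np.zeros(2 * window + 1)
    for chrom, dsub in dyads.groupby("chrom", sort=True):
        pos = np.sort(
            midpoints.loc[midpoints["chrom"] == chrom, "pos"].to_numpy())
        for d in dsub["dyad"].to_numpy():
            lo = np.searchsorted(pos, d - window, "left")
            hi = np.searchsorted(pos, d + window, "right")
            offs = pos[lo:hi] - (d - window)
            profile += np.bincount(offs, minlength=2 * window + 1)
    return profile / len(dyads)
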