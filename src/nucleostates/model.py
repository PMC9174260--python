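"""Quantitative nucleosome-state model: grouping, regularity, classification.

Core quantities per nucleosome i:

    lambda_i = S_i / W_i + omega * (mu - d_i)          (positioning factor)
    beta_i   = sum_k w_k * a_i^k * b_i                 (histone-mark factor)
    gamma    = (l_i b_i - l_{i+1} b_{i+1}) / sum_{n<=i} l_n b_n

where S is the peak area, W the footprint width, mu the local average spacing,
d the spacing to the next nucleosome, a^k the library-normalised mark-k signal
on the footprint and b the normalised occupancy signal.  Nucleosomes are
scanned left to right and merged into the running group while |gamma| stays
below 10% and the spacing does not exceed 350 bp.  Groups are summarised into
feature vectors and K-means-clustered into nine states, with clusters mapped
one-to-one onto the named states S1-S9 by an assignment-problem match against
a rule table distilled from the states' published descriptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linear_sum_assignment
from scipy.signal import welch
from scipy.special import erf
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .config import MARKS, STATES, default_archetypes

FEATURES = (["n_members", "spacing", "regularity", "dop",
             "frac_promoter", "frac_proximal", "frac_distal"]
            + [f"mark_{mk}" for mk in MARKS])


@dataclass
class WelchParams:
    nperseg: int = 512
    overlap: float = 0.5
    window: str = "hann"
    band_halfwidth: float = 0.10  # fractional band around 1/mu
    smooth_sd: float = 0.0        # bp; optional pre-smoothing (0 = raw counts)
    margin: int = 200             # bp added around the group span


@dataclass
class ModelParams:
    omega: float = 0.005
    mark_weights: dict[str, float] = field(
        default_factory=lambda: {mk: 1.0 for mk in MARKS})
    gamma_threshold: float = 0.10
    max_merge_spacing: float = 350.0
    mu_window: int = 10_000
    n_states: int = 9
    n_init: int = 50
    random_state: int = 0
    welch: WelchParams = field(default_factory=WelchParams)

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 < self.gamma_threshold < 1:
            raise ValueError("gamma_threshold must be in (0, 1)")
        if self.n_states < 2:
            raise ValueError("need at least two states")


# ---------------------------------------------------------------------------
# the three core factors
# ---------------------------------------------------------------------------

def positioning_factor(S, W, omega: float, mu, d):
    """lambda = S/W + omega * (mu - d); vectorised over numpy inputs."""
    S = np.asarray(S, float)
    W = np.asarray(W, float)
    if np.any(W <= 0):
        raise ValueError("footprint width W must be positive")
    return S / W + omega * (np.asarray(mu, float) - np.asarray(d, float))


def histone_factor(a: dict | pd.Series, b, weights: dict[str, float]):
    """beta = sum_k w_k * a^k * b for one nucleosome's mark profile."""
    b = float(b)
    if b < 0:
        raise ValueError("occupancy signal b must be >= 0")
    total = 0.0
    for mk, ak in dict(a).items():
        ak = float(ak)
        if ak < 0:
            raise ValueError(f"mark signal a^{mk} must be >= 0")
        total += weights.get(mk, 1.0) * ak * b
    return total


def similarity_ratio(products) -> float:
    """gamma for the last element of a lambda*beta product sequence.

    With products p_1..p_{i+1}, gamma = (p_i - p_{i+1}) / sum(p_1..p_i).
    Signed; callers merging on the 10% rule compare |gamma|.
    """
    p = np.asarray(products, float)
    if p.size < 2:
        raise ValueError("need at least two products")
    denom = p[:-1].sum()
    if denom == 0:
        raise ValueError("degenerate group: zero product sum")
    return float((p[-2] - p[-1]) / denom)


def local_mean_spacing(dyads: np.ndarray, window: int = 10_000,
                       lo: float = 150.0, hi: float = 350.0) -> np.ndarray:
    """Mean inter-dyad distance in a centred window, per nucleosome.

    Only distances within [lo, hi] bp count (larger gaps are inter-array
    deserts, not spacing); a nucleosome with no qualifying neighbour pair
    falls back to the chromosome-wide mean, or its own next-spacing.
    """
    dyads = np.asarray(dyads, float)
    n = dyads.size
    if n < 2:
        return np.full(n, np.nan)
    d = np.diff(dyads)
    valid = (d >= lo) & (d <= hi)
    vd = np.where(valid, d, 0.0)
    cnt = valid.astype(float)
    cs = np.concatenate([[0.0], np.cumsum(vd)])
    cc = np.concatenate([[0.0], np.cumsum(cnt)])
    half = window / 2
    # a spacing d_j (between j and j+1) is in i's window if both ends are
    left = np.searchsorted(dyads, dyads - half, "left")
    right = np.searchsorted(dyads, dyads + half, "right") - 1
    jlo = left
    jhi = np.maximum(right, left)  # spacing indices j in [jlo, jhi-1]
    tot = cs[np.maximum(jhi, jlo)] - cs[jlo]
    num = cc[np.maximum(jhi, jlo)] - cc[jlo]
    mu = np.divide(tot, num, out=np.full(n, np.nan), where=num > 0)
    if np.isnan(mu).any():
        fallback = vd.sum() / cnt.sum() if cnt.sum() > 0 else np.nan
        mu = np.where(np.isnan(mu), fallback, mu)
    return mu


# ---------------------------------------------------------------------------
# mark profiles
# ---------------------------------------------------------------------------

def compute_mark_profiles(nucleosomes: pd.DataFrame,
                          marks: dict[str, pd.DataFrame],
                          midpoints: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """Per-nucleosome library-normalised mark and occupancy signal.

    a^k = reads of mark k on the footprint / (library size / 1e6); b likewise
    for nucleosome occupancy reads (falling back to the called peak area
    when no midpoint track is given).
    """
    out = pd.DataFrame(index=nucleosomes.index)
    for mk, track in marks.items():
        out[f"a_{mk}"] = _footprint_counts(nucleosomes, track)
        lib = max(len(track), 1)
        out[f"a_{mk}"] *= 1e6 / lib
    if midpoints is not None:
        b = _footprint_counts(nucleosomes, midpoints)
        out["b"] = b * 1e6 / max(len(midpoints), 1)
    else:
        s = nucleosomes["score"].to_numpy(float)
        out["b"] = s * 1e6 / max(s.sum(), 1.0)
    return out


def _footprint_counts(nucleosomes: pd.DataFrame,
                      points: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(nucleosomes))
    for chrom, sub in nucleosomes.groupby("chrom", sort=True):
        pos = np.sort(points.loc[points["chrom"] == chrom, "pos"].to_numpy())
        lo = np.searchsorted(pos, sub["start"].to_numpy(), "left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), "left")
        counts[nucleosomes.index.get_indexer(sub.index)] = hi - lo
    return counts


def truth_mark_profiles(nucleosomes: pd.DataFrame) -> pd.DataFrame:
    """Mark profiles from a synthetic map's per-nucleosome true signal."""
    out = pd.DataFrame(index=nucleosomes.index)
    for mk in MARKS:
        col = f"sig_{mk}"
        sig = (nucleosomes[col].to_numpy(float)
               if col in nucleosomes else np.zeros(len(nucleosomes)))
        out[f"a_{mk}"] = sig * 1e6 / max(sig.sum(), 1.0)
    s = nucleosomes["score"].to_numpy(float)
    out["b"] = s * 1e6 / max(s.sum(), 1.0)
    return out


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

class NucleosomeGrouper(BaseEstimator):
    """Left-to-right gamma-rule grouping of called nucleosomes.

    ``transform`` expects a nucleosome table (chrom, dyad, start, end, score,
    width, dop) optionally joined with mark-profile columns (``a_<mark>``,
    ``b``).  Without profiles the histone factor is taken as 1 and grouping
    runs on the positioning factor alone.
    """

    def __init__(self, omega: float = 0.005, gamma_threshold: float = 0.10,
                 max_merge_spacing: float = 350.0, mu_window: int = 10_000,
                 mark_weights: dict[str, float] | None = None):
        self.omega = omega
        self.gamma_threshold = gamma_threshold
        self.max_merge_spacing = max_merge_spacing
        self.mu_window = mu_window
        self.mark_weights = mark_weights

    def fit(self, X: pd.DataFrame, y=None) -> "NucleosomeGrouper":
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of X with group_id, lambda, beta, product columns."""
        weights = self.mark_weights or {mk: 1.0 for mk in MARKS}
        out = []
        gid = 0
        for chrom, sub in X.groupby("chrom", sort=True):
            sub = sub.sort_values("dyad", kind="mergesort").copy()
            dyads = sub["dyad"].to_numpy(float)
            n = len(sub)
            mu = local_mean_spacing(dyads, self.mu_window)
            if n >= 2:
                d = np.concatenate([np.diff(dyads), [np.nan]])
                mu = np.where(np.isfinite(mu), mu, np.nanmedian(d))
                # the chromosome-last nucleosome and any whose next-neighbour
                # distance is an inter-array gap take d = mu (omega term 0)
                no_spacing = ~np.isfinite(d) | (d > self.max_merge_spacing)
                d[no_spacing] = mu[no_spacing]
            else:
                d = np.zeros(n)
                mu = np.zeros(n)
            lam = positioning_factor(sub["score"], sub["width"],
                                     self.omega, mu, d)
            beta = self._beta(sub, weights)
            prod = lam * beta
            group = np.zeros(n, dtype=np.int64)
            if n:
                group[0] = gid
                running = prod[0]
                for i in range(1, n):
                    gap = dyads[i] - dyads[i - 1]
                    merge = gap <= self.max_merge_spacing and _gamma_ok(
                        prod[i - 1], prod[i], running, self.gamma_threshold)
                    if merge:
                        running += prod[i]
                    else:
                        gid += 1
                        running = prod[i]
                    group[i] = gid
                gid += 1
            sub["lambda"] = lam
            sub["beta"] = beta
            sub["product"] = prod
            sub["group_id"] = group
            out.append(sub)
        if not out:
            res = X.copy()
            for c in ("lambda", "beta", "product", "group_id"):
                res[c] = []
            return res
        return pd.concat(out)

    @staticmethod
    def _beta(sub: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
        acols = [c for c in sub.columns if c.startswith("a_")]
        if not acols or "b" not in sub.columns:
            return np.ones(len(sub))
        b = sub["b"].to_numpy(float)
        if (b < 0).any():
            raise ValueError("occupancy signal b must be >= 0")
        beta = np.zeros(len(sub))
        for c in acols:
            a = sub[c].to_numpy(float)
            if (a < 0).any():
                raise ValueError(f"mark signal {c} must be >= 0")
            beta += weights.get(c[2:], 1.0) * a * b
        return beta


def _gamma_ok(p_prev: float, p_next: float, denom: float,
              threshold: float) -> bool:
    if denom == 0:
        return p_prev == p_next == 0  # identical degenerate profiles merge
    return abs((p_prev - p_next) / denom) < threshold


def group_nucleosomes(nucleosomes: pd.DataFrame,
                      profiles: pd.DataFrame | None = None,
                      params: ModelParams | None = None) -> pd.DataFrame:
    """Functional wrapper: join profiles, group, return annotated table."""
    params = params or ModelParams()
    X = nucleosomes if profiles is None else nucleosomes.join(profiles)
    return NucleosomeGrouper(
        omega=params.omega, gamma_threshold=params.gamma_threshold,
        max_merge_spacing=params.max_merge_spacing,
        mu_window=params.mu_window,
        mark_weights=params.mark_weights).fit(X).transform(X)


def summarize_groups(grouped: pd.DataFrame) -> pd.DataFrame:
    """One row per group: span, member count, mean intra-group spacing."""
    rows = []
    for gid, sub in grouped.groupby("group_id", sort=True):
        dyads = sub["dyad"].to_numpy()
        rows.append({
            "group_id": gid,
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["start"].min()),
            "end": int(sub["end"].max()),
            "n_members": len(sub),
            "spacing": float(np.diff(dyads).mean()) if len(sub) > 1 else np.nan,
            "dop": float(sub["dop"].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regularity
# ---------------------------------------------------------------------------

def regularity_score(signal: np.ndarray, mu: float,
                     params: WelchParams | None = None) -> float:
    """Array periodicity: Welch PSD power near 1/mu over the median PSD.

    ``signal`` is a mean-detrended 1-bp density over the array span.  The
    band is 1/mu +- 10% (fractional); band power is read off the PSD by
    interpolation because the Welch frequency grid is coarser than the band.
    """
    params = params or WelchParams()
    x = np.asarray(signal, float)
    if x.size < 8 or mu <= 0 or not np.isfinite(mu):
        return 0.0
    x = x - x.mean()
    nper = min(params.nperseg, x.size)
    freqs, psd = welch(x, fs=1.0, window=params.window, nperseg=nper,
                       noverlap=int(nper * params.overlap))
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    med = np.median(psd)
    if med <= 0:
        return 0.0
    f0 = 1.0 / mu
    band = np.linspace(f0 * (1 - params.band_halfwidth),
                       f0 * (1 + params.band_halfwidth), 50)
    band_power = float(np.interp(band, freqs, psd).mean())
    return band_power / float(med)


def group_regularity(grouped: pd.DataFrame, midpoints: pd.DataFrame,
                     params: WelchParams | None = None) -> pd.Series:
    """Regularity score per group from the smoothed midpoint density.

    Single-nucleosome groups score 0 (periodicity undefined).
    """
    params = params or WelchParams()
    scores = {}
    mids_by_chrom = {c: np.sort(s["pos"].to_numpy())
                     for c, s in midpoints.groupby("chrom", sort=True)}
    for gid, sub in grouped.groupby("group_id", sort=True):
        if len(sub) < 2:
            scores[gid] = 0.0
            continue
        chrom = sub["chrom"].iloc[0]
        pos = mids_by_chrom.get(chrom, np.array([], dtype=np.int64))
        lo = int(sub["start"].min()) - params.margin
        hi = int(sub["end"].max()) + params.margin
        i0 = np.searchsorted(pos, lo, "left")
        i1 = np.searchsorted(pos, hi, "left")
        counts = np.bincount(pos[i0:i1] - lo, minlength=hi - lo).astype(float)
        dens = (gaussian_filter1d(counts, params.smooth_sd, mode="constant")
                if params.smooth_sd > 0 else counts)
        mu = float(np.diff(np.sort(sub["dyad"].to_numpy())).mean())
        scores[gid] = regularity_score(dens, mu, params)
    return pd.Series(scores, name="regularity")


# ---------------------------------------------------------------------------
# feature table and state rules
# ---------------------------------------------------------------------------

def group_feature_table(grouped: pd.DataFrame,
                        genes: pd.DataFrame | None = None,
                        midpoints: pd.DataFrame | None = None,
                        params: ModelParams | None = None) -> pd.DataFrame:
    """Standard feature vector per group for state classification."""
    params = params or ModelParams()
    feats = summarize_groups(grouped).set_index("group_id")
    feats["spacing"] = feats["spacing"].fillna(feats["spacing"].mean())
    if midpoints is not None:
        feats["regularity"] = group_regularity(grouped, midpoints,
                                               params.welch)
    else:
        feats["regularity"] = 0.0
    # region composition of member dyads
    if genes is not None and len(genes):
        from .calling import assign_region
        lab = assign_region(
            grouped.rename(columns={"dyad": "pos"})[["chrom", "pos"]], genes)
        lab["group_id"] = grouped["group_id"].to_numpy()
        for name in ("Promoter", "Proximal", "Distal"):
            frac = (lab["region"] == name).groupby(
                lab["group_id"]).mean()
            feats[f"frac_{name.lower()}"] = frac
    else:
        for name in ("promoter", "proximal", "distal"):
            feats[f"frac_{name}"] = 0.0
    for mk in MARKS:
        col = f"a_{mk}"
        if col in grouped.columns:
            feats[f"mark_{mk}"] = grouped.groupby("group_id")[col].mean()
        else:
            feats[f"mark_{mk}"] = 0.0
    return feats[[c for c in FEATURES] + ["chrom", "start", "end"]]


def default_state_rules() -> pd.DataFrame:
    """Archetype feature record per named state (the labelling rule table).

    Distils the published state descriptions: S1 promoter/active marks,
    S2 short 180.43 bp spacing with 1-4 members, S3 primed promoter/proximal,
    S4 crowding 5-20-member arrays at 210.64 bp with repressive marks,
    S5 down-promoter and most regular, S6 short-spacing restricted,
    S7 distal steady, S8 fuzzy (low positioning/regularity), S9 unknown.
    """
    arch = default_archetypes()
    spacing_default = {"S3": 187.0, "S7": 187.0, "S9": 187.0}
    regularity = {"S1": 12.0, "S2": 9.85, "S3": 12.0, "S4": 12.0,
                  "S5": 21.0, "S6": 12.0, "S7": 12.0, "S8": 4.0, "S9": 10.0}
    rows = {}
    for s in STATES:
        a = arch[s]
        sd = a.positioning_noise_sd * np.sqrt(2.0)
        dop = float(erf(20.0 / sd) / erf(73.0 / sd)) if sd > 0 else 1.0
        row = {
            "n_members": (a.n_members[0] + a.n_members[1]) / 2.0,
            "spacing": (a.spacing_mean if a.spacing_mean is not None
                        else spacing_default[s]),
            "regularity": regularity[s],
            "dop": dop,
            "frac_promoter": a.region_weights[0],
            "frac_proximal": a.region_weights[1],
            "frac_distal": a.region_weights[2],
        }
        for mk in MARKS:
            row[f"mark_{mk}"] = a.mark_intensity.get(mk, 0.0)
        rows[s] = row
    return pd.DataFrame(rows).T[FEATURES]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class StateClassifier(BaseEstimator, ClusterMixin):
    """K-means over z-scored group features, clusters mapped onto S1-S9.

    Fitted attributes: ``labels_`` (cluster index per group), ``states_``
    (mapped state label per group), ``state_map_`` (cluster -> state),
    ``kmeans_``, ``feature_names_``, ``mean_``, ``scale_``.
    """

    def __init__(self, n_states: int = 9, n_init: int = 50,
                 random_state: int = 0, rules: pd.DataFrame | None = None):
        self.n_states = n_states
        self.n_init = n_init
        self.random_state = random_state
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None) -> "StateClassifier":
        feats = X[[c for c in FEATURES if c in X.columns]].astype(float)
        if len(feats) < self.n_states:
            raise ValueError(
                f"need at least {self.n_states} groups, got {len(feats)}")
        keep = feats.std(ddof=0) > 0
        if not keep.all():
            warnings.warn("dropping zero-variance features: "
                          f"{list(feats.columns[~keep])}")
        feats = feats.loc[:, keep]
        self.feature_names_ = list(feats.columns)
        self.mean_ = feats.mean()
        self.scale_ = feats.std(ddof=0)
        Z = (feats - self.mean_) / self.scale_
        self.kmeans_ = KMeans(n_clusters=self.n_states, init="k-means++",
                              n_init=self.n_init,
                              random_state=self.random_state)
        self.labels_ = self.kmeans_.fit_predict(Z.to_numpy())
        self.state_map_ = self._map_clusters()
        self.states_ = np.array([self.state_map_[c] for c in self.labels_])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = ((X[self.feature_names_].astype(float) - self.mean_)
             / self.scale_)
        return np.array([self.state_map_[c]
                         for c in self.kmeans_.predict(Z.to_numpy())])

    def _map_clusters(self) -> dict[int, str]:
        rules = self.rules if self.rules is not None else default_state_rules()
        if len(rules) != self.n_states:
            raise ValueError("rule table must have one row per state")
        cols = [c for c in self.feature_names_ if c in rules.columns]
        centers = pd.DataFrame(self.kmeans_.cluster_centers_,
                               columns=self.feature_names_)[cols]
        # undo z-scoring, then z-score across rows on both sides
        centers = centers * self.scale_[cols] + self.mean_[cols]
        cz = _rowwise_z(centers)
        rz = _rowwise_z(rules[cols].astype(float))
        cost = ((cz.to_numpy()[:, None, :] - rz.to_numpy()[None, :, :]) ** 2
                ).sum(axis=2)
        ci, si = linear_sum_assignment(cost)
        states = list(rules.index)
        return {int(c): states[s] for c, s in zip(ci, si)}


def _rowwise_z(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0.0, 1.0)
    return (df - df.mean()) / sd


def classify_states(features: pd.DataFrame,
                    params: ModelParams | None = None,
                    rules: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit the classifier and return group -> cluster -> state assignments."""
    params = params or ModelParams()
    clf = StateClassifier(n_states=params.n_states, n_init=params.n_init,
                          random_state=params.random_state, rules=rules)
    clf.fit(features)
    return pd.DataFrame({
        "group_id": features.index,
        "cluster": clf.labels_,
        "state": clf.states_,
    }).set_index("group_id")
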