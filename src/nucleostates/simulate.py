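"""Synthetic MNase-style data with known ground truth.

Generates every input the downstream pipeline consumes: phased nucleosome
arrays drawn from nine state archetypes, fragment midpoints, per-mark read
tracks, matched Veh/DHT condition pairs drawn from a transition matrix,
1-bp paired binding borders, gene models and a differential-expression table.

Layout model
------------
Regions occupy fixed, non-overlapping slots of ``region_pitch`` bp, one array
and one gene per region.  The gene is placed so that the array centre falls in
the region class (Promoter / Proximal / Distal) drawn from the archetype's
region weights, and the pitch guarantees that the nearest upstream-covering
TSS of any array is its own gene, so region-class ground truth is exact.

Noise model
-----------
Within an array, occupancy and mark coverage are coherent: each array has a
lognormal amplitude, each member a small relative jitter.  The nucleosome
table carries *true* peak areas; Poisson-level sampling noise appears in the
emitted fragment midpoints, which is where the dyad caller sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import (
    MARKS,
    MARK_DETECTION_LEVEL,
    NFR,
    STATES,
    SyntheticConfig,
)

CONDITIONS = ("Veh", "DHT")

#: Margin between a slot boundary and the first/last permissible dyad.
SLOT_MARGIN = 2_000
#: sd (bp) of mark-read placement around the dyad.
MARK_READ_SD = 30.0


class CapacityError(ValueError):
    """Genome too short for the requested number of regions."""


@dataclass
class SyntheticMap:
    """One condition's generated data plus its ground truth."""

    condition: str
    nucleosomes: pd.DataFrame
    regions: pd.DataFrame
    genes: pd.DataFrame
    midpoints: pd.DataFrame | None = None
    marks: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ConditionPair:
    veh: SyntheticMap
    dht: SyntheticMap
    regions: pd.DataFrame  # region_id, chrom, state_veh, state_dht


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _auto_genome(config: SyntheticConfig, n_regions: int) -> list[tuple[str, int]]:
    return [("chr1", (n_regions + 2) * config.region_pitch)]


def _slots(config: SyntheticConfig, n_regions: int) -> pd.DataFrame:
    """Assign each region a fixed genomic slot; error if genome too small."""
    genome = config.genome or _auto_genome(config, n_regions)
    rows = []
    for chrom, length in genome:
        # skip slot 0 so upstream gene windows never go negative
        for k in range(1, length // config.region_pitch):
            rows.append((chrom, k * config.region_pitch))
            if len(rows) == n_regions:
                break
        if len(rows) == n_regions:
            break
    if len(rows) < n_regions:
        raise CapacityError(
            f"genome holds {len(rows)} region slots, {n_regions} requested")
    df = pd.DataFrame(rows, columns=["chrom", "slot_start"])
    df["region_id"] = np.arange(n_regions)
    return df


def _resolve_states(config: SyntheticConfig, n_regions: int | None,
                    states, rng: np.random.Generator) -> np.ndarray:
    if states is None:
        if n_regions is None:
            n_regions = config.n_regions
        names = list(config.state_priors)
        p = np.array([config.state_priors[s] for s in names])
        return rng.choice(names, size=n_regions, p=p / p.sum())
    if isinstance(states, dict):
        out = np.concatenate(
            [np.repeat(s, c) for s, c in states.items()]) if states else np.array([], str)
        return out
    return np.asarray(states, dtype=object)


def _theoretical_dop(noise_sd: float) -> float:
    """Expected +-20 / +-73 bp midpoint concentration for Gaussian jitter."""
    if noise_sd <= 0:
        return 1.0
    s = noise_sd * np.sqrt(2.0)
    return float(erf(20.0 / s) / erf(73.0 / s))


# ---------------------------------------------------------------------------
# core map generation
# ---------------------------------------------------------------------------

def generate_nucleosome_map(
    config: SyntheticConfig,
    condition: str = "Veh",
    states=None,
    n_regions: int | None = None,
    seed: int | None = None,
    emit_reads: bool = True,
    emit_marks: bool = True,
    _slots_df: pd.DataFrame | None = None,
    _rng: np.random.Generator | None = None,
    _genes: pd.DataFrame | None = None,
) -> SyntheticMap:
    """Generate one condition's nucleosome map with ground truth.

    ``states`` may be None (drawn from the configured priors), a dict
    ``{state: count}``, or an explicit per-region sequence (``NFR`` entries
    yield empty regions).  Deterministic given config, seed and arguments.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if _rng is None:
        root = np.random.SeedSequence(
            config.rng_seed if seed is None else seed)
        _rng = np.random.default_rng(
            root.spawn(3)[CONDITIONS.index(condition)])
    rng = _rng

    states = _resolve_states(config, n_regions, states, rng)
    n_reg = len(states)
    slots = _slots_df if _slots_df is not None else _slots(config, n_reg)
    if len(slots) != n_reg:
        raise ValueError("slot table does not match number of regions")

    nuc_parts: list[pd.DataFrame] = []
    region_rows: list[pd.DataFrame] = []
    max_span = config.region_pitch - 2 * SLOT_MARGIN

    for state in STATES:  # fixed order => deterministic rng consumption
        mask = states == state
        m = int(mask.sum())
        if m == 0:
            continue
        arch = config.state_archetypes[state]
        lo, hi = arch.n_members
        n_mem = rng.integers(lo, hi + 1, size=m)
        total = int(n_mem.sum())

        # intra-array spacings (first member has spacing slot 0)
        spac = np.zeros(total)
        first_idx = np.cumsum(n_mem) - n_mem
        inner = np.ones(total, bool)
        inner[first_idx] = False
        n_inner = int(inner.sum())
        if n_inner:
            # each array has one characteristic repeat length (NRL); members
            # jitter tightly around it
            if arch.spacing_mean is None:
                nrl = config.spacing_global.sample(rng, m)
            else:
                nrl = rng.normal(arch.spacing_mean, arch.spacing_sd, m)
            draws = rng.normal(np.repeat(nrl, n_mem)[inner],
                               arch.spacing_jitter_sd)
            spac[inner] = np.clip(draws, 150.0, None)
        cs = np.cumsum(spac)
        rel = cs - np.repeat(cs[first_idx], n_mem)
        span = rel[np.cumsum(n_mem) - 1]
        if (span > max_span).any():
            raise CapacityError(
                f"{state} array span exceeds region pitch "
                f"{config.region_pitch}; increase region_pitch")

        slot_start = slots.loc[mask, "slot_start"].to_numpy()
        chroms = slots.loc[mask, "chrom"].to_numpy()
        region_ids = slots.loc[mask, "region_id"].to_numpy()
        first_dyad = slot_start + SLOT_MARGIN
        dyads = (np.repeat(first_dyad, n_mem) + rel).round().astype(np.int64)

        # coherent within-array occupancy
        amp = rng.lognormal(0.0, config.array_amplitude_sigma, m)
        jit = rng.normal(0.0, config.occupancy_sigma, total)
        counts = np.maximum(
            1, np.round(config.reads_per_nucleosome
                        * np.repeat(amp, n_mem) * np.exp(jit))).astype(np.int64)

        noise_sd = (config.positioning_noise_sd
                    if config.positioning_noise_sd is not None
                    else arch.positioning_noise_sd)
        dop = _theoretical_dop(noise_sd)

        # per-array mark intensity scalar; coherent counts within the array
        u = rng.lognormal(0.0, arch.intensity_sigma, m)
        mark_cols = {}
        carrier = {}
        for mk in MARKS:
            inten = arch.mark_intensity.get(mk, 0.0)
            per_arr = np.round(config.mark_reads * inten * u).astype(np.int64)
            mark_cols[f"sig_{mk}"] = np.repeat(per_arr, n_mem)
            carrier[f"has_{mk}"] = inten * u > MARK_DETECTION_LEVEL

        nuc = pd.DataFrame({
            "chrom": np.repeat(chroms, n_mem),
            "dyad": dyads,
            "start": dyads - 73,
            "end": dyads + 74,
            "score": counts.astype(float),
            "width": 147,
            "dop": dop,
            "noise_sd": noise_sd,
            "region_id": np.repeat(region_ids, n_mem),
            "state": state,
            **mark_cols,
        })
        nuc_parts.append(nuc)

        last_dyad = dyads[np.cumsum(n_mem) - 1]
        region_rows.append(pd.DataFrame({
            "region_id": region_ids,
            "chrom": chroms,
            "slot_start": slot_start,
            "slot_end": slot_start + config.region_pitch,
            "state": state,
            "n_members": n_mem,
            "array_start": first_dyad - 73,
            "array_end": last_dyad + 74,
            "center": (first_dyad + last_dyad) // 2,
            **carrier,
        }))

    nfr_mask = states == NFR
    if nfr_mask.any():
        region_rows.append(pd.DataFrame({
            "region_id": slots.loc[nfr_mask, "region_id"].to_numpy(),
            "chrom": slots.loc[nfr_mask, "chrom"].to_numpy(),
            "slot_start": slots.loc[nfr_mask, "slot_start"].to_numpy(),
            "slot_end": slots.loc[nfr_mask, "slot_start"].to_numpy()
            + config.region_pitch,
            "state": NFR,
            "n_members": 0,
            "array_start": -1, "array_end": -1, "center": -1,
            **{f"has_{mk}": False for mk in MARKS},
        }))

    nucs = (pd.concat(nuc_parts, ignore_index=True)
            if nuc_parts else _empty_nucleosomes())
    nucs = nucs.sort_values(["chrom", "dyad"], kind="mergesort",
                            ignore_index=True)
    regions = (pd.concat(region_rows, ignore_index=True)
               .sort_values("region_id", kind="mergesort", ignore_index=True))

    genes = (_genes if _genes is not None
             else _genes_for_regions(regions, rng, config.state_archetypes))
    regions = regions.merge(
        genes[["region_id", "gene", "strand", "tss", "tes", "region_class"]],
        on="region_id", how="left")

    midpoints = None
    marks: dict[str, pd.DataFrame] = {}
    if emit_reads:
        midpoints = _emit_midpoints(nucs, rng)
    if emit_marks:
        marks = _emit_marks(nucs, rng)
    return SyntheticMap(condition, nucs, regions, genes, midpoints, marks)


def _empty_nucleosomes() -> pd.DataFrame:
    cols = {"chrom": str, "dyad": np.int64, "start": np.int64,
            "end": np.int64, "score": float, "width": np.int64,
            "dop": float, "noise_sd": float, "region_id": np.int64,
            "state": str}
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in cols.items()})
    for mk in MARKS:
        df[f"sig_{mk}"] = pd.Series(dtype=np.int64)
    return df


def _genes_for_regions(regions: pd.DataFrame, rng: np.random.Generator,
                       archetypes) -> pd.DataFrame:
    """One gene per region, placed so the array centre hits its drawn class."""
    n = len(regions)
    classes = np.empty(n, dtype=object)
    offsets = np.zeros(n, dtype=np.int64)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    cls_draw = rng.random(n)
    prox_off = rng.integers(3200, 4501, size=n)
    dist_off = rng.integers(9000, 20001, size=n)
    for i, (state, center) in enumerate(
            zip(regions["state"], regions["center"])):
        if state == NFR or center < 0:
            classes[i] = "Distal"
            offsets[i] = dist_off[i]
            continue
        w = (archetypes[state].region_weights
             if state in archetypes else (1 / 3,) * 3)
        c = cls_draw[i]
        if c < w[0]:
            classes[i], offsets[i] = "Promoter", 0
        elif c < w[0] + w[1]:
            classes[i], offsets[i] = "Proximal", prox_off[i]
        else:
            classes[i], offsets[i] = "Distal", dist_off[i]
    center = regions["center"].to_numpy().copy()
    no_arr = center < 0
    center[no_arr] = (regions.loc[no_arr, "slot_start"]
                      + (regions["slot_end"] - regions["slot_start"]).loc[no_arr] // 2)
    sign = np.where(strands == "+", 1, -1)
    tss = center + sign * offsets
    gene_len = 2_000
    tes = tss + sign * gene_len
    return pd.DataFrame({
        "gene": [f"G{r:05d}" for r in regions["region_id"]],
        "chrom": regions["chrom"].to_numpy(),
        "strand": strands,
        "tss": tss.astype(np.int64),
        "tes": tes.astype(np.int64),
        "region_id": regions["region_id"].to_numpy(),
        "region_class": classes,
    })


def _emit_midpoints(nucs: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    counts = nucs["score"].round().astype(np.int64).to_numpy()
    pos = np.repeat(nucs["dyad"].to_numpy(), counts).astype(float)
    sds = np.repeat(nucs["noise_sd"].to_numpy(), counts)
    jitter = np.where(sds > 0, rng.normal(0.0, 1.0, pos.size) * sds, 0.0)
    out = pd.DataFrame({
        "chrom": np.repeat(nucs["chrom"].to_numpy(), counts),
        "pos": np.maximum(0, np.round(pos + jitter)).astype(np.int64),
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort",
                           ignore_index=True)


def _emit_marks(nucs: pd.DataFrame,
                rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    out = {}
    for mk in MARKS:
        col = f"sig_{mk}"
        counts = nucs[col].to_numpy() if col in nucs else np.zeros(len(nucs), np.int64)
        counts = counts.astype(np.int64)
        pos = np.repeat(nucs["dyad"].to_numpy(), counts).astype(float)
        pos = np.maximum(
            0, np.round(pos + rng.normal(0.0, MARK_READ_SD, pos.size)))
        out[mk] = pd.DataFrame({
            "chrom": np.repeat(nucs["chrom"].to_numpy(), counts),
            "pos": pos.astype(np.int64),
        }).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# condition pairs
# ---------------------------------------------------------------------------

def generate_condition_pair(
    config: SyntheticConfig,
    states=None,
    n_regions: int | None = None,
    seed: int | None = None,
    emit_reads: bool = True,
    emit_marks: bool = True,
) -> ConditionPair:
    """Matched Veh/DHT maps; DHT states drawn from the transition matrix."""
    root = np.random.SeedSequence(config.rng_seed if seed is None else seed)
    rng_veh, rng_dht, rng_tr = (np.random.default_rng(s) for s in root.spawn(3))

    veh_states = _resolve_states(config, n_regions, states, rng_tr)
    n_reg = len(veh_states)
    slots = _slots(config, n_reg)

    tm = config.transition_matrix
    missing = set(np.unique(veh_states)) - set(tm.index)
    if missing:
        raise ValueError(f"transition matrix lacks rows for {sorted(missing)}")
    dest = np.asarray(tm.columns, dtype=object)
    dht_states = np.empty(n_reg, dtype=object)
    for s in tm.index:  # fixed order
        mask = veh_states == s
        if mask.any():
            p = tm.loc[s].to_numpy(float)
            dht_states[mask] = rng_tr.choice(dest, size=int(mask.sum()),
                                             p=p / p.sum())

    veh = generate_nucleosome_map(
        config, "Veh", states=veh_states, _slots_df=slots, _rng=rng_veh,
        emit_reads=emit_reads, emit_marks=emit_marks)
    dht = generate_nucleosome_map(
        config, "DHT", states=dht_states, _slots_df=slots, _rng=rng_dht,
        emit_reads=emit_reads, emit_marks=emit_marks,
        _genes=veh.genes)
    regions = pd.DataFrame({
        "region_id": np.arange(n_reg),
        "chrom": slots["chrom"].to_numpy(),
        "state_veh": veh_states,
        "state_dht": dht_states,
    })
    return ConditionPair(veh, dht, regions)


def truth_groups(smap: SyntheticMap) -> pd.DataFrame:
    """Ground-truth groups (one per emitted region) for the switching stage."""
    reg = smap.regions
    occ = reg[reg["n_members"] > 0]
    return pd.DataFrame({
        "group_id": occ["region_id"].to_numpy(),
        "chrom": occ["chrom"].to_numpy(),
        "start": occ["array_start"].to_numpy(),
        "end": occ["array_end"].to_numpy(),
        "n_members": occ["n_members"].to_numpy(),
        "state": occ["state"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# borders
# ---------------------------------------------------------------------------

def generate_borders(
    config: SyntheticConfig,
    nucleosomes: pd.DataFrame,
    condition: str = "Veh",
    n_pairs: int = 5_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired 1-bp borders with ground-truth nucleosome assignment.

    A configured fraction of pairs is centred on nucleosomes (S3/S4 carriers
    get |dyad offset| in the edge window with ``edge_mass`` probability);
    the rest land in inter-array deserts, >130 bp from any dyad.
    """
    bm = config.border_model
    frac_on = bm.fraction_on_nucleosome.get(condition)
    if frac_on is None:
        raise ValueError(f"no on-nucleosome fraction for condition {condition}")
    root = np.random.SeedSequence(
        [config.rng_seed if seed is None else seed,
         7 + CONDITIONS.index(condition)])
    rng = np.random.default_rng(root)

    n_nucs = len(nucleosomes)
    if n_nucs == 0 and frac_on > 0:
        raise CapacityError("no nucleosomes available for on-nucleosome pairs")

    on = rng.random(n_pairs) < frac_on
    n_on = int(on.sum())
    centers = np.empty(n_pairs, dtype=np.int64)
    nuc_idx = np.full(n_pairs, -1, dtype=np.int64)
    offset = np.zeros(n_pairs, dtype=np.int64)
    state = np.full(n_pairs, "", dtype=object)

    if n_on:
        idx = rng.integers(0, n_nucs, size=n_on)
        dyads = nucleosomes["dyad"].to_numpy()[idx]
        st = nucleosomes["state"].to_numpy()[idx]
        is_edge_state = np.isin(st, np.asarray(bm.edge_states, dtype=object))
        at_edge = rng.random(n_on) < bm.edge_mass
        lo, hi = bm.edge_window
        # edge states bind the footprint edge; others toward the middle
        mag = np.where(
            is_edge_state & at_edge,
            rng.integers(lo, hi + 1, size=n_on),
            rng.integers(0, bm.mid_offset_max + 1, size=n_on))
        sign = rng.choice(np.array([-1, 1]), size=n_on)
        off = sign * mag
        centers[on] = dyads + off
        nuc_idx[on] = idx
        offset[on] = off
        state[on] = st

    n_off = n_pairs - n_on
    chrom = np.full(n_pairs, nucleosomes["chrom"].iloc[0]
                    if n_nucs else "chr1", dtype=object)
    if n_on:
        chrom[on] = nucleosomes["chrom"].to_numpy()[nuc_idx[on]]
    if n_off:
        off_chrom, off_pos = _desert_positions(nucleosomes, n_off, rng,
                                               clearance=130)
        centers[~on] = off_pos
        chrom[~on] = off_chrom
    gaps = bm.gap_shift + rng.poisson(bm.gap_lambda, size=n_pairs)
    left = centers - gaps // 2
    right = left + gaps
    out = pd.DataFrame({
        "chrom": chrom,
        "left": left,
        "right": right,
        "pair_id": [f"{condition}_pb{i:06d}" for i in range(n_pairs)],
        "score": 0,
        "condition": condition,
        "on_nucleosome": on,
        "true_nuc": nuc_idx,
        "true_offset": offset,
        "true_state": state,
    })
    return out.sort_values(["chrom", "left"], kind="mergesort",
                           ignore_index=True)


def _desert_positions(nucleosomes: pd.DataFrame, n: int,
                      rng: np.random.Generator,
                      clearance: int = 130) -> tuple[np.ndarray, np.ndarray]:
    """Sample positions >= clearance bp away from every dyad."""
    ivs = []  # (chrom, lo, hi)
    if len(nucleosomes) == 0:
        ivs.append(("chr1", 1_000, 1_000_000))
    for chrom, sub in nucleosomes.groupby("chrom", sort=True):
        d = sub["dyad"].to_numpy()
        lo = np.concatenate([[d[0] - 5_000], d + clearance])
        hi = np.concatenate([d - clearance, [d[-1] + 5_000]])
        keep = hi > lo
        for a, b in zip(lo[keep], hi[keep]):
            ivs.append((chrom, int(a), int(b)))
    lens = np.array([b - a for _, a, b in ivs], dtype=float)
    cum = np.cumsum(lens)
    u = rng.random(n) * cum[-1]
    which = np.searchsorted(cum, u, side="right")
    within = (u - (cum[which] - lens[which])).astype(np.int64)
    pos = np.array([ivs[w][1] for w in which], dtype=np.int64) + within
    chroms = np.array([ivs[w][0] for w in which], dtype=object)
    return chroms, pos


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def generate_gene_tables(
    config: SyntheticConfig,
    seed: int | None = None,
    genes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standalone non-overlapping gene models plus a DE table.

    If ``genes`` is given (e.g. a map's per-region genes) only the DE table is
    drawn, keyed by those gene ids.  A configurable fraction of genes passes
    the strict |log2FC| > 1 and p < 0.05 filter.
    """
    root = np.random.SeedSequence(
        [config.rng_seed if seed is None else seed, 11])
    rng = np.random.default_rng(root)
    if genes is None:
        n = config.n_genes
        pitch = config.gene_length + 4_000
        starts = 3_000 + np.arange(n, dtype=np.int64) * pitch
        strands = rng.choice(np.array(["+", "-"]), size=n)
        sign = np.where(strands == "+", 1, -1)
        tss = np.where(strands == "+", starts, starts + config.gene_length)
        genes = pd.DataFrame({
            "gene": [f"G{i:05d}" for i in range(n)],
            "chrom": "chr1",
            "strand": strands,
            "tss": tss.astype(np.int64),
            "tes": (tss + sign * config.gene_length).astype(np.int64),
        })
    n = len(genes)
    if n == 0:
        return genes, pd.DataFrame(columns=["gene", "log2fc", "p"])
    sig = rng.random(n) < config.de_significant_fraction
    lfc = np.where(
        sig,
        rng.choice(np.array([-1.0, 1.0]), size=n)
        * (1.0 + 1e-6 + rng.exponential(0.8, size=n)),
        rng.uniform(-1.0, 1.0, size=n))
    p = np.where(sig, rng.uniform(0.0, 0.0499, size=n),
                 rng.uniform(0.0, 1.0, size=n))
    de = pd.DataFrame({"gene": genes["gene"].to_numpy(),
                       "log2fc": lfc, "p": p})
    return genes.reset_index(drop=True), de
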