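"""Lipid structure metrics: thickness maps, S_CH order parameters, zones.

The bilayer thickness is the separation along the bilayer normal between
paired phosphate headgroups of opposite leaflets (each phosphate paired with
its nearest partner in the other leaflet); pair midpoints are accumulated on
a 6 x 6 grid of 22 A bins in the disc xy-plane, one grid per leaflet, and the
two grids are averaged.  Order parameters are S_CH = (3 cos^2(theta) - 1)/2
with theta the angle between a C-H bond and the bilayer normal, averaged over
the bonds of each carbon and the two tails.  Lipids within 10 A of any
scaffold-protein bead form the rim zone, the rest the core zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

GRID_N = 6
GRID_BIN = 22.0


@dataclass
class LipidFrame:
    """Per-lipid structural records of one frame, in the disc frame (z = normal).

    ``ch_vectors`` has shape (n_lipids, 2 tails, n_carbons, 3), unit vectors.
    ``particles`` lists every bead of each lipid (used for zone assignment).
    """

    leaflet: np.ndarray  # (n,) "top" | "bottom"
    phosphate: np.ndarray  # (n, 3), A
    ch_vectors: np.ndarray
    particles: list[np.ndarray]
    msp: np.ndarray  # (m, 3) scaffold bead positions

    def __post_init__(self):
        norms = np.linalg.norm(self.ch_vectors, axis=-1)
        if np.any(norms < 1e-9):
            raise ValueError("zero-length C-H vector")
        self.ch_vectors = self.ch_vectors / norms[..., None]

    @property
    def n_lipids(self) -> int:
        return len(self.leaflet)

    @property
    def n_carbons(self) -> int:
        return self.ch_vectors.shape[2]


@dataclass
class GridMap:
    """6 x 6 binned map; empty bins are NaN with zero count."""

    values: np.ndarray
    counts: np.ndarray
    bin_size: float = GRID_BIN

    def __post_init__(self):
        if self.values.shape != (GRID_N, GRID_N) or self.counts.shape != (GRID_N, GRID_N):
            raise ValueError("grid must be 6 x 6")

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def _grid_accumulate(xy: np.ndarray, values: np.ndarray, center: np.ndarray) -> GridMap:
    half = GRID_N * GRID_BIN / 2.0
    idx = np.floor((xy - center[None, :] + half) / GRID_BIN).astype(int)
    ok = np.all((idx >= 0) & (idx < GRID_N), axis=1)
    sums = np.zeros((GRID_N, GRID_N))
    counts = np.zeros((GRID_N, GRID_N))
    np.add.at(sums, (idx[ok, 0], idx[ok, 1]), values[ok])
    np.add.at(counts, (idx[ok, 0], idx[ok, 1]), 1.0)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GridMap(vals, counts)


def thickness_map(frame: LipidFrame) -> GridMap:
    """Leaflet-averaged 6 x 6 map of phosphate-pair thickness, A."""
    top = frame.phosphate[frame.leaflet == "top"]
    bot = frame.phosphate[frame.leaflet == "bottom"]
    if len(top) == 0 or len(bot) == 0:
        raise ValueError("both leaflets must contain lipids")
    center = frame.phosphate[:, :2].mean(axis=0)
    grids = []
    for ref, other in ((top, bot), (bot, top)):
        tree = cKDTree(other)
        _, j = tree.query(ref)  # nearest partner; pairs with replacement
        partner = other[j]
        thick = np.abs(ref[:, 2] - partner[:, 2])
        mid = 0.5 * (ref[:, :2] + partner[:, :2])
        grids.append(_grid_accumulate(mid, thick, center))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        vals = np.nanmean(np.stack([g.values for g in grids]), axis=0)
    counts = grids[0].counts + grids[1].counts
    return GridMap(np.where(counts > 0, vals, np.nan), counts)


def sch_order(frame: LipidFrame) -> np.ndarray:
    """S_CH per lipid and carbon, tail-averaged; shape (n_lipids, n_carbons)."""
    cos_t = frame.ch_vectors[..., 2]
    s = 0.5 * (3.0 * cos_t**2 - 1.0)
    return s.mean(axis=1)


def zone_partition(frame: LipidFrame, cutoff: float = 10.0) -> np.ndarray:
    """Label each lipid 'rim' (any bead within cutoff of a scaffold bead) or 'core'."""
    if len(frame.msp) == 0:
        raise ValueError("scaffold bead positions required")
    tree = cKDTree(frame.msp)
    labels = np.empty(frame.n_lipids, dtype="U4")
    for i, beads in enumerate(frame.particles):
        d = tree.query(np.atleast_2d(beads))[0].min()
        labels[i] = "rim" if d <= cutoff else "core"
    return labels


def sch_map(frame: LipidFrame) -> GridMap:
    """6 x 6 map of carbon-averaged S_CH at the lipid phosphate positions."""
    s = sch_order(frame).mean(axis=1)
    center = frame.phosphate[:, :2].mean(axis=0)
    return _grid_accumulate(frame.phosphate[:, :2], s, center)


@dataclass
class LipidProfiles:
    thickness: GridMap
    order: GridMap
    s_by_carbon: dict = field(default_factory=dict)  # zone -> (n_carbons,) array


def ensemble_lipid_profiles(frames, weights, cutoff: float = 10.0) -> LipidProfiles:
    """Weight-averaged lipid maps and per-zone S_CH(carbon) curves.

    Grid bins empty in some frames contribute only where occupied (the
    weighted average runs over frames with data in that bin); bins empty in
    every frame stay NaN.
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    thick_sum = np.zeros((GRID_N, GRID_N))
    thick_wt = np.zeros((GRID_N, GRID_N))
    s_sum = np.zeros((GRID_N, GRID_N))
    s_wt = np.zeros((GRID_N, GRID_N))
    counts_t = np.zeros((GRID_N, GRID_N))
    counts_s = np.zeros((GRID_N, GRID_N))
    n_carb = frames[0].n_carbons
    zone_sum = {"rim": np.zeros(n_carb), "core": np.zeros(n_carb)}
    zone_wt = {"rim": 0.0, "core": 0.0}
    for frame, wj in zip(frames, w):
        if wj == 0.0:
            continue
        tm = thickness_map(frame)
        occ = tm.occupied
        thick_sum[occ] += wj * tm.values[occ]
        thick_wt[occ] += wj
        counts_t += tm.counts
        sm = sch_map(frame)
        occ = sm.occupied
        s_sum[occ] += wj * sm.values[occ]
        s_wt[occ] += wj
        counts_s += sm.counts
        zones = zone_partition(frame, cutoff)
        s = sch_order(frame)
        for z in ("rim", "core"):
            sel = zones == z
            if np.any(sel):
                zone_sum[z] += wj * s[sel].mean(axis=0)
                zone_wt[z] += wj
    with np.errstate(invalid="ignore"):
        thick = np.where(thick_wt > 0, thick_sum / np.maximum(thick_wt, 1e-300), np.nan)
        smap = np.where(s_wt > 0, s_sum / np.maximum(s_wt, 1e-300), np.nan)
    curves = {z: zone_sum[z] / zone_wt[z] for z in ("rim", "core") if zone_wt[z] > 0}
    return LipidProfiles(
        thickness=GridMap(thick, counts_t),
        order=GridMap(smap, counts_s),
        s_by_carbon=curves,
    )
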