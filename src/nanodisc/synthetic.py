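"""Toy nanodisc ensembles and pseudo-experiments with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: an ensemble of coarse-grained discs whose elliptical cross-section
fluctuates in magnitude and major-axis direction (area-preserving, mimicking
a fixed lipid count), a lipid patch with planted radial thickness and
order-parameter profiles, noisy absolute-scale scattering computed from a
known "true" weight vector, and NOE-style upper bounds consistent with that
truth.  Every planted quantity is recorded, so recovery can be scored
exactly; all randomness flows through seeds carried in the spec.

Bead contrasts are chosen to mimic the two experimental situations: X-rays
see a negative tail core against positive heads and belt (core-shell),
neutrons in D2O see all components positive (bulk contrast).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .coords import CoordinateSet, Ensemble
from .curves import ScatteringCurve
from .debye import debye_intensity, frame_intensity
from .lipids import LipidFrame
from .noe import NoeTable, NoeRecord, frame_distances, noe_effective_distance
from .reweight import ObservableSet

DEFAULT_CONTRASTS = {
    "xray": {"belt": 1.0, "lipid-head": 1.5, "lipid-tail": -1.0, "tag": 1.0},
    "neutron": {"belt": 1.2, "lipid-head": 1.0, "lipid-tail": 0.8, "tag": 1.2},
}


@dataclass
class ToySpec:
    """Generator settings; defaults define the reference study conditions."""

    n_frames: int = 100
    n_belt: int = 36  # beads per belt ring (two stacked rings)
    a0: float = 30.0  # base semi-axes of the lipid patch, A
    b0: float = 30.0
    s_eps: float = 0.2  # ellipticity scale: eps = 1 + |N(0, s_eps)|
    belt_offset: float = 4.0  # belt ring radius beyond the patch edge, A
    ring_z: float = 6.0  # belt rings at +/- ring_z, A
    lipid_spacing: float = 9.0  # in-plane lipid lattice constant, A
    thickness_core: float = 40.0  # planted phosphate-phosphate distance, A
    thickness_rim: float = 34.0
    rim_width: float = 10.0  # planted rim band: lipids this close to the belt
    s_core: float = 0.22  # planted S_CH plateau, core zone
    s_rim: float = 0.08
    n_carbons: int = 12
    n_tail_beads: int = 3
    jitter: float = 0.3  # per-bead positional noise, A
    contrasts: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CONTRASTS.items()})
    f_rel: float = 0.02  # relative scattering noise
    noise_floor_frac: float = 1e-4  # floor as a fraction of I(0)
    q_min: float = 0.01
    q_max: float = 0.25
    n_q: int = 60
    noe_count: int = 30
    noe_margin: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (self.a0 >= self.b0 > 0):
            raise ValueError("require a0 >= b0 > 0")
        if self.s_eps < 0:
            raise ValueError("s_eps must be non-negative")
        if self.f_rel <= 0:
            raise ValueError("f_rel must be positive")
        if self.n_frames < 1 or self.n_belt < 8:
            raise ValueError("need at least 1 frame and 8 belt beads per ring")

    @property
    def qgrid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)


def _base_lipid_grid(spec: ToySpec) -> np.ndarray:
    """Fixed lattice of lipid sites in unit-disc coordinates."""
    du = spec.lipid_spacing / math.sqrt(spec.a0 * spec.b0)
    k = int(math.floor(1.0 / du)) + 1
    ax = np.arange(-k, k + 1) * du
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    # fill the patch nearly to its edge: outer lipids must lie within the
    # rim band (they contact the belt in a real disc)
    return pts[np.hypot(pts[:, 0], pts[:, 1]) <= 0.97]


def _build_frame(spec: ToySpec, eps: float, phi: float, rng) -> tuple:
    """One disc frame; returns (CoordinateSet, LipidFrame, record dict)."""
    ab = spec.a0 * spec.b0
    a = math.sqrt(ab * eps)
    b = math.sqrt(ab / eps)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])

    t = 2.0 * math.pi * np.arange(spec.n_belt) / spec.n_belt
    ring_xy = np.column_stack([(a + spec.belt_offset) * np.cos(t),
                               (b + spec.belt_offset) * np.sin(t)]) @ rot.T
    belt = np.concatenate([
        np.column_stack([ring_xy, np.full(spec.n_belt, +spec.ring_z)]),
        np.column_stack([ring_xy, np.full(spec.n_belt, -spec.ring_z)]),
    ])

    grid = _base_lipid_grid(spec)
    lipid_xy = (grid * np.array([a, b])) @ rot.T
    d_belt = np.min(
        np.linalg.norm(lipid_xy[:, None, :] - ring_xy[None, :, :], axis=-1), axis=1
    )
    is_rim = d_belt <= spec.rim_width
    thick = np.where(is_rim, spec.thickness_rim, spec.thickness_core)

    n_site = len(lipid_xy)
    n_carb, n_tail = spec.n_carbons, spec.n_tail_beads
    frac = np.arange(n_carb) / max(n_carb - 1, 1)
    prof = {True: spec.s_rim * (1 - 0.4 * frac), False: spec.s_core * (1 - 0.4 * frac)}

    phosphate, leaflet, particles, ch_all = [], [], [], []
    xyz_parts = [belt + rng.normal(scale=spec.jitter, size=belt.shape)]
    names = [np.array(["BB"] * len(belt))]
    resn = [np.array(["MSP"] * len(belt))]
    resid = [np.concatenate([np.arange(1, spec.n_belt + 1)] * 2)]
    chain = [np.array(["A"] * spec.n_belt + ["B"] * spec.n_belt)]
    role = [np.array(["belt"] * len(belt))]
    lip_counter = 0
    for sign, leaf in ((+1.0, "top"), (-1.0, "bottom")):
        for i in range(n_site):
            zp = sign * thick[i] / 2.0
            head = np.array([lipid_xy[i, 0], lipid_xy[i, 1], zp])
            dz = (abs(zp) - 1.0) / (n_tail + 1)
            tails = np.array([
                [head[0], head[1], sign * (abs(zp) - (m + 1) * dz)]
                for m in range(n_tail)
            ])
            beads = np.vstack([head, tails])
            beads = beads + rng.normal(scale=spec.jitter, size=beads.shape)
            lip_counter += 1
            phosphate.append(beads[0])
            leaflet.append(leaf)
            particles.append(beads)
            s_prof = prof[bool(is_rim[i])]
            cos_t = np.sqrt((2.0 * s_prof + 1.0) / 3.0)
            az = rng.uniform(0, 2 * math.pi, size=(2, n_carb))
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
            ch = np.stack([
                sin_t * np.cos(az), sin_t * np.sin(az),
                np.broadcast_to(cos_t, az.shape)], axis=-1)
            ch_all.append(ch)
            xyz_parts.append(beads)
            names.append(np.array(["P"] + [f"C{m+1}" for m in range(n_tail)]))
            resn.append(np.array(["PHO"] + ["TAI"] * n_tail))
            resid.append(np.full(1 + n_tail, lip_counter))
            chain.append(np.array(["L"] * (1 + n_tail)))
            role.append(np.array(["lipid-head"] + ["lipid-tail"] * n_tail))

    cs = CoordinateSet(
        xyz=np.vstack(xyz_parts),
        atom_name=np.concatenate(names),
        res_name=np.concatenate(resn),
        res_id=np.concatenate(resid),
        chain_id=np.concatenate(chain),
        role=np.concatenate(role),
    )
    lf = LipidFrame(
        leaflet=np.array(leaflet),
        phosphate=np.array(phosphate),
        ch_vectors=np.array(ch_all),
        particles=particles,
        msp=np.vstack([xyz_parts[0]]),
    )
    record = {"eps": eps, "phi": phi, "a": a, "b": b}
    return cs, lf, record


def _assemble(spec: ToySpec, eps_arr, phi_arr, rng) -> Ensemble:
    frames, lipid_frames, recs = [], [], []
    for eps, phi in zip(eps_arr, phi_arr):
        cs, lf, rec = _build_frame(spec, float(eps), float(phi), rng)
        frames.append(cs)
        lipid_frames.append(lf)
        recs.append(rec)
    ens = Ensemble(frames=frames)
    ens.meta.update(
        eps=np.array([r["eps"] for r in recs]),
        phi=np.array([r["phi"] for r in recs]),
        a=np.array([r["a"] for r in recs]),
        b=np.array([r["b"] for r in recs]),
        lipid_frames=lipid_frames,
        spec=spec,
    )
    return ens


def generate_toy_ensemble(spec: ToySpec) -> tuple[Ensemble, np.ndarray]:
    """Ensemble with fluctuating elliptical cross-section; uniform true weights."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    eps = 1.0 + np.abs(rng.normal(0.0, spec.s_eps, size=spec.n_frames)) \
        if spec.s_eps > 0 else np.ones(spec.n_frames)
    phi = rng.uniform(0.0, math.pi, size=spec.n_frames)
    ens = _assemble(spec, eps, phi, rng)
    true_w = np.full(spec.n_frames, 1.0 / spec.n_frames)
    return ens, true_w


def bead_contrasts(ensemble: Ensemble, spec: ToySpec, contrast: str) -> np.ndarray:
    table = spec.contrasts[contrast]
    return np.array([table[r] for r in ensemble.frames[0].role])


def synthesize_scattering(
    ensemble: Ensemble,
    true_weights,
    spec: ToySpec,
    contrast: str = "xray",
    seed_offset: int = 1,
) -> tuple[ScatteringCurve, ScatteringCurve]:
    """Noisy pseudo-experiment plus the underlying noise-free truth curve."""
    q = spec.qgrid
    b = bead_contrasts(ensemble, spec, contrast)
    coords = [f.xyz for f in ensemble.frames]
    truth = debye_intensity(coords, b, true_weights, q)
    sigma = spec.f_rel * truth.intensity + spec.noise_floor_frac * truth.intensity.max()
    rng = np.random.default_rng(spec.seed + seed_offset)
    noisy = truth.intensity + rng.normal(scale=sigma)
    curve = ScatteringCurve(q=q, intensity=noisy, sigma=sigma, contrast=contrast,
                            label=f"synthetic-{contrast}")
    truth = ScatteringCurve(q=q, intensity=truth.intensity, sigma=sigma,
                            contrast=contrast, label=f"true-{contrast}")
    return curve, truth


def saxs_observables(ensemble: Ensemble, spec: ToySpec, curve: ScatteringCurve,
                     contrast: str = "xray") -> ObservableSet:
    """Per-frame Debye intensities as equality restraints against a curve."""
    b = bead_contrasts(ensemble, spec, contrast)
    F = np.column_stack([
        frame_intensity(f.xyz, b, curve.q) for f in ensemble.frames
    ])
    return ObservableSet(F=F, F_exp=curve.intensity, sigma=curve.sigma,
                         kind="equality", label="saxs")


def synthesize_noes(
    ensemble: Ensemble, true_weights, spec: ToySpec, seed_offset: int = 2
) -> NoeTable:
    """Upper-bound table on belt bead pairs, consistent with the true weights."""
    n_belt_beads = 2 * spec.n_belt
    pairs = [(i, j) for i in range(n_belt_beads) for j in range(i + 1, n_belt_beads)
             if (abs(i % spec.n_belt - j % spec.n_belt) % spec.n_belt) >= spec.n_belt // 6]
    if spec.noe_count > len(pairs):
        raise ValueError("noe_count exceeds available belt bead pairs")
    rng = np.random.default_rng(spec.seed + seed_offset)
    chosen = [pairs[k] for k in rng.choice(len(pairs), spec.noe_count, replace=False)]
    table = NoeTable([NoeRecord((i,), (j,), 1.0) for i, j in chosen])
    dmat = frame_distances(table, ensemble.frames)
    d_eff = noe_effective_distance(dmat, true_weights)
    table.records = [
        NoeRecord((i,), (j,), float(d * (1.0 + spec.noe_margin)))
        for (i, j), d in zip(chosen, d_eff)
    ]
    return table


def noe_observables(ensemble: Ensemble, table: NoeTable,
                    rel_sigma: float = 0.05) -> ObservableSet:
    """NOE bounds as BME restraints on the linear observable R^-3.

    An upper bound on the effective distance is a lower bound on <R^-3>,
    hence kind='lower_bound'.
    """
    dmat = frame_distances(table, ensemble.frames)
    F = dmat**-3
    F_exp = table.bounds**-3.0
    return ObservableSet(F=F, F_exp=F_exp, sigma=rel_sigma * F_exp,
                         kind="lower_bound", label="noe")


@dataclass
class TruthReport:
    planted_populations: list[float]
    cluster: list[int]
    eps: list[float]
    phi: list[float]
    true_weights: list[float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthReport":
        return cls(**json.loads(text))


@dataclass
class Benchmark:
    ensemble: Ensemble
    true_weights: np.ndarray
    saxs: ScatteringCurve
    saxs_truth: ScatteringCurve
    saxs_obs: ObservableSet
    noe_table: NoeTable
    noe_obs: ObservableSet
    truth: TruthReport


def planted_benchmark(
    spec: ToySpec | None = None,
    cluster_eps: tuple[float, float] = (1.05, 1.45),
    cluster_phi: tuple[float, float] = (0.0, math.pi / 2),
    planted_populations: tuple[float, float] = (0.3, 0.7),
    eps_spread: float = 0.02,
    phi_spread: float = 0.08,
) -> Benchmark:
    """Two-cluster benchmark: elliptical clusters with orthogonal major axes.

    The prior is uniform over frames; the pseudo-experiments are generated
    under the planted (non-uniform) cluster populations, so reweighting
    against them should recover those populations.
    """
    spec = spec or ToySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n0 = n // 2
    cluster = np.array([0] * n0 + [1] * (n - n0))
    eps = np.where(
        cluster == 0,
        cluster_eps[0] + rng.normal(0, eps_spread, n),
        cluster_eps[1] + rng.normal(0, eps_spread, n),
    )
    eps = np.clip(eps, 1.0, None)
    phi = np.where(
        cluster == 0,
        cluster_phi[0] + rng.normal(0, phi_spread, n),
        cluster_phi[1] + rng.normal(0, phi_spread, n),
    )
    ens = _assemble(spec, eps, phi, rng)
    ens.meta["cluster"] = cluster
    true_w = np.where(cluster == 0, planted_populations[0] / n0,
                      planted_populations[1] / (n - n0))
    true_w = true_w / true_w.sum()
    saxs, saxs_truth = synthesize_scattering(ens, true_w, spec, "xray")
    sobs = saxs_observables(ens, spec, saxs, "xray")
    table = synthesize_noes(ens, true_w, spec)
    nobs = noe_observables(ens, table)
    truth = TruthReport(
        planted_populations=list(planted_populations),
        cluster=cluster.tolist(),
        eps=eps.tolist(),
        phi=phi.tolist(),
        true_weights=true_w.tolist(),
        seed=spec.seed,
    )
    return Benchmark(ens, true_w, saxs, saxs_truth, sobs, table, nobs, truth)
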