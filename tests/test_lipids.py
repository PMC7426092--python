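"""Lipid metrics: thickness maps, S_CH order parameters, rim/core zones."""

import numpy as np
import pytest

from nanodisc.lipids import (GridMap, LipidFrame, ensemble_lipid_profiles,
                             sch_order, thickness_map, zone_partition)


def _flat_frame(thickness=40.0, n_side=10, spacing=8.0, s_value=0.2,
                n_carbons=6, rim_thickness=None, thin_beyond_x=None,
                belt_radius=None):
    """Square patch of lipids, both leaflets.

    Optional planted thinning for |x| >= ``thin_beyond_x``; optional circular
    scaffold belt (two bead rings at z = +/-10) at ``belt_radius``, with the
    patch clipped inside it.  Each lipid carries tail beads spanning z so that
    proximity to the belt is lateral, as for real lipids.
    """
    ax = (np.arange(n_side) - (n_side - 1) / 2) * spacing
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    if belt_radius is not None:
        xy = xy[np.hypot(xy[:, 0], xy[:, 1]) <= belt_radius - 2.0]
    n = len(xy)
    leaflet, phos, parts, ch = [], [], [], []
    cos_t = np.sqrt((2 * s_value + 1) / 3)
    sin_t = np.sqrt(1 - cos_t**2)
    for sign, leaf in ((+1, "top"), (-1, "bottom")):
        for i in range(n):
            t = thickness
            if rim_thickness is not None and thin_beyond_x is not None \
                    and abs(xy[i, 0]) >= thin_beyond_x:
                t = rim_thickness
            zp = sign * t / 2
            p = np.array([xy[i, 0], xy[i, 1], zp])
            tails = np.array([[xy[i, 0], xy[i, 1], z]
                              for z in np.linspace(zp, sign * 1.0, 4)])
            leaflet.append(leaf)
            phos.append(p)
            parts.append(tails)
            az = np.linspace(0, 2 * np.pi, 2 * n_carbons, endpoint=False)
            az = az.reshape(2, n_carbons)
            ch.append(np.stack([sin_t * np.cos(az), sin_t * np.sin(az),
                                np.full(az.shape, cos_t)], axis=-1))
    t_ring = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    rad = belt_radius if belt_radius is not None else 1e6  # effectively no belt
    ring = np.column_stack([rad * np.cos(t_ring), rad * np.sin(t_ring),
                            np.full_like(t_ring, 10.0)])
    msp = np.vstack([ring, ring * [1, 1, -1]])
    return LipidFrame(leaflet=np.array(leaflet), phosphate=np.array(phos),
                      ch_vectors=np.array(ch), particles=parts, msp=msp)


class TestThickness:
    def test_uniform_bilayer_constant_map(self):
        gm = thickness_map(_flat_frame(thickness=40.0))
        occ = gm.occupied
        assert occ.any()
        np.testing.assert_allclose(gm.values[occ], 40.0, atol=1e-9)
        assert np.all(np.isnan(gm.values[~occ]))

    def test_single_lipid_pair_degenerate(self):
        frame = _flat_frame(n_side=1, thickness=37.0)
        gm = thickness_map(frame)
        assert gm.counts.sum() == 2  # one pair seen from each leaflet
        np.testing.assert_allclose(gm.values[gm.occupied], 37.0)

    def test_planted_edge_thinning_recovered(self):
        """Thinner lipids planted near the patch edge show up in the map."""
        frame = _flat_frame(thickness=40.0, rim_thickness=34.0, thin_beyond_x=20.0,
                            n_side=12, spacing=7.0)
        gm = thickness_map(frame)
        edge_cols = np.concatenate([gm.values[[1, 4], 2:4].ravel()])
        core_cols = gm.values[2:4, 2:4].ravel()
        # x-bins [22, 44] hold only thinned lipids; central bins only core ones
        assert np.nanmean(core_cols) - np.nanmean(edge_cols) >= 4.0

    def test_empty_leaflet_rejected(self):
        frame = _flat_frame(n_side=2)
        frame.leaflet[:] = "top"
        with pytest.raises(ValueError):
            thickness_map(frame)


class TestOrder:
    def test_parallel_bonds_give_one(self):
        f = _flat_frame(s_value=1.0, n_side=2)
        np.testing.assert_allclose(sch_order(f), 1.0, atol=1e-12)

    def test_perpendicular_bonds_give_minus_half(self):
        f = _flat_frame(n_side=2)
        f.ch_vectors[..., :] = 0.0
        f.ch_vectors[..., 0] = 1.0  # all C-H in-plane
        np.testing.assert_allclose(sch_order(f), -0.5, atol=1e-12)

    def test_isotropic_null(self, rng):
        v = rng.normal(size=(1, 2, 50000, 3))
        f = _flat_frame(n_side=1)
        f2 = LipidFrame(leaflet=np.array(["top"]), phosphate=f.phosphate[:1],
                        ch_vectors=v[:1], particles=f.particles[:1], msp=f.msp)
        s = sch_order(f2)
        assert np.abs(s.mean()) < 0.01

    def test_range_bounds(self, rng):
        v = rng.normal(size=(5, 2, 8, 3))
        f = _flat_frame(n_side=3)
        f5 = LipidFrame(leaflet=f.leaflet[:5], phosphate=f.phosphate[:5],
                        ch_vectors=v, particles=f.particles[:5], msp=f.msp)
        s = sch_order(f5)
        assert np.all(s >= -0.5 - 1e-12) and np.all(s <= 1.0 + 1e-12)

    def test_zero_vector_rejected(self):
        f = _flat_frame(n_side=2)
        bad = f.ch_vectors.copy()
        bad[0, 0, 0] = 0.0
        with pytest.raises(ValueError):
            LipidFrame(leaflet=f.leaflet, phosphate=f.phosphate, ch_vectors=bad,
                       particles=f.particles, msp=f.msp)


class TestZones:
    def test_labels_match_direct_distance_check(self):
        frame = _flat_frame(belt_radius=40.0, n_side=10, spacing=8.0)
        labels = zone_partition(frame, cutoff=10.0)
        for i, lab in enumerate(labels):
            d = min(np.linalg.norm(frame.msp[:, None] - frame.particles[i][None],
                                   axis=-1).min() for _ in (0,))
            assert lab == ("rim" if d <= 10.0 else "core")

    def test_close_and_far_lipids(self):
        frame = _flat_frame(belt_radius=30.0, n_side=8, spacing=8.0)
        labels = zone_partition(frame, cutoff=10.0)
        assert "rim" in labels and "core" in labels


class TestEnsembleProfiles:
    def test_single_frame_equals_per_frame(self):
        f = _flat_frame(belt_radius=40.0)
        prof = ensemble_lipid_profiles([f], [1.0])
        tm = thickness_map(f)
        np.testing.assert_allclose(prof.thickness.values[tm.occupied],
                                   tm.values[tm.occupied])

    def test_planted_rim_disorder_recovered(self):
        frames = []
        for _ in range(3):
            f = _flat_frame(belt_radius=40.0, n_side=12, spacing=7.0)
            labels = zone_partition(f, cutoff=10.0)
            rim = labels == "rim"
            # plant low order at the rim: tilt rim C-H bonds into the plane
            f.ch_vectors[rim] = 0.0
            f.ch_vectors[rim, ..., 0] = 1.0
            frames.append(f)
        prof = ensemble_lipid_profiles(frames, np.full(3, 1 / 3))
        assert np.all(prof.s_by_carbon["core"] > prof.s_by_carbon["rim"])

    def test_linearity_in_weights(self):
        f1 = _flat_frame(thickness=40.0, belt_radius=40.0)
        f2 = _flat_frame(thickness=34.0, belt_radius=40.0)
        p1 = ensemble_lipid_profiles([f1, f2], [1.0, 0.0])
        p2 = ensemble_lipid_profiles([f1, f2], [0.0, 1.0])
        mix = ensemble_lipid_profiles([f1, f2], [0.3, 0.7])
        occ = mix.thickness.occupied
        np.testing.assert_allclose(
            mix.thickness.values[occ],
            0.3 * p1.thickness.values[occ] + 0.7 * p2.thickness.values[occ],
            rtol=1e-9)

    def test_lipid_order_permutation_invariant(self):
        f = _flat_frame(belt_radius=40.0)
        perm = np.random.default_rng(0).permutation(f.n_lipids)
        g = LipidFrame(leaflet=f.leaflet[perm], phosphate=f.phosphate[perm],
                       ch_vectors=f.ch_vectors[perm],
                       particles=[f.particles[i] for i in perm], msp=f.msp)
        a, b = thickness_map(f), thickness_map(g)
        occ = a.occupied
        np.testing.assert_allclose(a.values[occ], b.values[occ])
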