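"""Analytical scattering model of the elliptical nanodisc.

The intensity is the orientation average of the coherent sum of elliptical-
cylinder amplitudes for the tail core, the two headgroup layers, and the
hollow belt cylinder, optionally with Gaussian-coil terms for two disordered
purification tags:

    I(q) = scale * n * < | sum_c drho_c V_c A_c(q, alpha, psi) |^2 >
           * exp(-q^2 sigma_r^2)  +  background

with the elliptical-cylinder amplitude

    A(q, alpha, psi) = [2 J1(u)/u] * sinc(q L cos(alpha) / 2),
    u = q r(psi) sin(alpha),   r(psi) = sqrt(a^2 sin^2(psi) + b^2 cos^2(psi))

(major axis a along x).  The orientation average runs over alpha in [0, pi/2]
(weight sin(alpha)) and psi in [0, pi/2], evaluated by Gauss-Legendre
quadrature.  Intensities are absolute scale: SLDs in fm/A^3, volumes in A^3,
number density n in 1/cm^3, so I is in 1/cm via fm^2 = 1e-26 cm^2.

A matching bead discretization of the same geometry supports the Debye-sum
cross-check and the pair-distance distribution function p(r).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import j1
from numpy.polynomial.legendre import leggauss
from numpy.polynomial.hermite import hermgauss

from .composition import MolecularComposition, ContrastSet, component_slds
from .curves import ScatteringCurve
from .geometry import NanodiscParams, DerivedDimensions, derive_dimensions

FM2_TO_CM2 = 1e-26


def _quad_nodes(n_alpha: int, n_psi: int):
    """Tensor Gauss-Legendre nodes/weights for the two orientation angles."""
    xa, wa = leggauss(n_alpha)
    alpha = 0.25 * math.pi * (xa + 1.0)
    w_alpha = 0.25 * math.pi * wa * np.sin(alpha)  # sin(alpha) d(alpha), ~int = 1
    xp, wp = leggauss(n_psi)
    psi = 0.25 * math.pi * (xp + 1.0)
    w_psi = 0.25 * math.pi * wp / (0.5 * math.pi)  # uniform, normalized
    A, P = np.meshgrid(alpha, psi, indexing="ij")
    W = np.outer(w_alpha, w_psi).ravel()
    return A.ravel(), P.ravel(), W / W.sum()


def _disc_amp(q, sin_a, cos_a, r_psi, length):
    """Normalized elliptical-cylinder amplitude on (q x orientation) grids."""
    u = q[:, None] * (r_psi * sin_a)[None, :]
    w = q[:, None] * (cos_a * 0.5 * length)[None, :]
    ju = np.ones_like(u)
    nz = u > 1e-9
    ju[nz] = 2.0 * j1(u[nz]) / u[nz]
    return ju * np.sinc(w / math.pi)


def _sum_amplitude(q, params, dims, slds, n_alpha, n_psi):
    """Coherent disc amplitude sum over components, (nq, n_orient), plus weights."""
    a, b, w = dims.r_major, dims.r_minor, dims.w_belt
    alpha, psi, wq = _quad_nodes(n_alpha, n_psi)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    sin_p, cos_p = np.sin(psi), np.cos(psi)

    def r_of(amaj, bmin):
        return np.sqrt((amaj * sin_p) ** 2 + (bmin * cos_p) ** 2)

    v_tail = math.pi * a * b * dims.h_tails
    v_hlip = math.pi * a * b * dims.h_lipid
    v_head = v_hlip - v_tail
    v_out = math.pi * (a + w) * (b + w) * params.h_belt
    v_in = math.pi * a * b * params.h_belt
    v_belt = v_out - v_in

    amp_tail = _disc_amp(q, sin_a, cos_a, r_of(a, b), dims.h_tails)
    amp_hlip = _disc_amp(q, sin_a, cos_a, r_of(a, b), dims.h_lipid)
    amp_head = (v_hlip * amp_hlip - v_tail * amp_tail) / v_head
    amp_bout = _disc_amp(q, sin_a, cos_a, r_of(a + w, b + w), params.h_belt)
    amp_bin = _disc_amp(q, sin_a, cos_a, r_of(a, b), params.h_belt)
    amp_belt = (v_out * amp_bout - v_in * amp_bin) / v_belt

    total = (
        slds["tails"] * v_tail * amp_tail
        + slds["head"] * v_head * amp_head
        + slds["belt"] * v_belt * amp_belt
    )
    return total, wq


def coil_debye(x):
    """Gaussian-coil (Debye) form factor P(x), x = (q Rg)^2.

    Series below x = 0.01 avoids cancellation in exp(-x) + x - 1.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-2
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0
    xl = x[~small]
    out[~small] = 2.0 * (np.exp(-xl) + xl - 1.0) / xl**2
    return out


def coil_psi(x):
    """Coil amplitude factor psi(x) = (1 - exp(-x)) / x for cross terms."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-2
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs**2 / 6.0 - xs**3 / 24.0
    xl = x[~small]
    out[~small] = (1.0 - np.exp(-xl)) / xl
    return out


def model_intensity(
    qgrid,
    params: NanodiscParams,
    composition: MolecularComposition | None = None,
    contrast: str = "xray",
    solvent: str | None = None,
    n_tags: int | None = None,
    concentration: float | None = None,
    n_alpha: int = 64,
    n_psi: int = 32,
) -> ScatteringCurve:
    """Absolute-scale model intensity on a q grid.

    ``solvent`` defaults to H2O for X-rays and D2O for neutrons.  ``n_tags``
    overrides the composition's tag count.  If ``concentration`` (1/cm^3) is
    absent, the number density is absorbed into the scale factor.
    """
    q = np.asarray(qgrid, dtype=float)
    if len(q) == 0 or np.any(q < 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be non-negative and strictly increasing")
    comp = composition if composition is not None else MolecularComposition()
    params.validate()
    if solvent is None:
        solvent = "h2o" if contrast == "xray" else "d2o"
    slds = component_slds(comp, contrast, solvent)
    dims = derive_dimensions(params, comp)
    n_tags = comp.n_tag if n_tags is None else n_tags

    amp, wq = _sum_amplitude(q, params, dims, slds, n_alpha, n_psi)
    i_disc = (amp**2) @ wq
    mean_amp = amp @ wq

    intensity = i_disc
    if n_tags > 0:
        beta = slds["tag"] * comp.tag.volume
        x = (q * params.rg_tag) ** 2
        # tags attach at the outer belt rim, mid-height; isotropic phase factor
        r_att = 0.5 * (dims.r_major + dims.r_minor) + dims.w_belt
        ph = np.sinc(q * r_att / math.pi)
        psi_c = coil_psi(x)
        intensity = (
            i_disc
            + n_tags * beta**2 * coil_debye(x)
            + 2.0 * n_tags * beta * psi_c * ph * mean_amp
            + n_tags * (n_tags - 1) * (beta * psi_c * ph) ** 2
        )

    scale = params.scale_xray if contrast == "xray" else params.scale_neutron
    n_dens = 1.0 if concentration is None else concentration
    i_abs = (
        scale * n_dens * FM2_TO_CM2 * intensity * np.exp(-(q**2) * params.sigma_r**2)
        + params.background
    )
    return ScatteringCurve(
        q=q, intensity=i_abs, sigma=np.ones_like(q), contrast=contrast, label="model"
    )


def polydisperse_intensity(
    qgrid,
    params: NanodiscParams,
    composition: MolecularComposition | None = None,
    contrast: str = "xray",
    n_hermite: int = 9,
    **kwargs,
) -> ScatteringCurve:
    """Model intensity averaged over N_lipid ~ Normal(N, sigma_lip * N).

    Gauss-Hermite quadrature; nodes at non-positive lipid numbers are dropped
    (with a warning if they carry more than 1% of the mass).  A_head and eps
    are held fixed, so the disc axes rescale as sqrt(N).
    """
    params.validate()
    if params.sigma_lip == 0:
        return model_intensity(qgrid, params, composition, contrast, **kwargs)
    nodes, wts = hermgauss(n_hermite)
    sd = params.sigma_lip * params.n_lipid
    n_vals = params.n_lipid + math.sqrt(2.0) * sd * nodes
    wts = wts / math.sqrt(math.pi)
    keep = n_vals > 0
    if wts[~keep].sum() > 0.01:
        warnings.warn("sigma_lip truncation discards > 1% of the lipid-number mass")
    n_vals, wts = n_vals[keep], wts[keep] / wts[keep].sum()
    q = np.asarray(qgrid, dtype=float)
    acc = np.zeros_like(q)
    for n_lip, wt in zip(n_vals, wts):
        p_i = NanodiscParams(**{**params.__dict__, "n_lipid": n_lip, "sigma_lip": 0.0})
        acc += wt * model_intensity(q, p_i, composition, contrast, **kwargs).intensity
    return ScatteringCurve(q=q, intensity=acc, sigma=np.ones_like(q), contrast=contrast,
                           label="model-polydisperse")


def _ellipse_cells(a: float, b: float, spacing: float):
    """Near-equal-area cells tiling the full ellipse (elliptical-polar grid).

    With x = a s cos(t), y = b s sin(t) the area element is a b s ds dt, so
    splitting each ring uniformly in t is exact.  Returns (xy, area_weights)
    with weights summing to 1.
    """
    n_rings = max(1, round(b / spacing))
    perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    pts, wts = [], []
    for k in range(n_rings):
        s0, s1 = k / n_rings, (k + 1) / n_rings
        s_mid = math.sqrt(0.5 * (s0**2 + s1**2))
        n_t = max(4, round(s_mid * perim / spacing))
        t = 2.0 * math.pi * (np.arange(n_t) + 0.5) / n_t
        pts.append(np.column_stack([a * s_mid * np.cos(t), b * s_mid * np.sin(t)]))
        wts.append(np.full(n_t, (s1**2 - s0**2) / n_t))
    return np.vstack(pts), np.concatenate(wts)


def _annulus_cells(a: float, b: float, w: float, spacing: float):
    """Area-weighted cells tiling the elliptical annulus of width w.

    Parametrization ((a + w u) cos t, (b + w u) sin t) has area Jacobian
    w [(b + w u) cos^2 t + (a + w u) sin^2 t]; cell weights follow it so the
    angular mass distribution is correct (weights normalized to sum 1).
    """
    n_rings = max(1, round(w / spacing))
    perim = math.pi * (3 * (a + b + 2 * w) - math.sqrt(
        (3 * (a + w) + b + w) * (a + w + 3 * (b + w))))
    pts, wts = [], []
    for k in range(n_rings):
        u_mid = (k + 0.5) / n_rings
        n_t = max(8, round(perim / spacing))
        t = 2.0 * math.pi * (np.arange(n_t) + 0.5) / n_t
        pts.append(np.column_stack([(a + w * u_mid) * np.cos(t),
                                    (b + w * u_mid) * np.sin(t)]))
        jac = (b + w * u_mid) * np.cos(t) ** 2 + (a + w * u_mid) * np.sin(t) ** 2
        wts.append(jac / n_rings)
    wts = np.concatenate(wts)
    return np.vstack(pts), wts / wts.sum()


def _z_layers(z_lo: float, z_hi: float, spacing: float) -> np.ndarray:
    """Layer centers that tile [z_lo, z_hi] exactly (adjusted spacing)."""
    nz = max(1, round((z_hi - z_lo) / spacing))
    dz = (z_hi - z_lo) / nz
    return z_lo + (np.arange(nz) + 0.5) * dz


def discretize_model(
    params: NanodiscParams,
    composition: MolecularComposition | None = None,
    spacing: float = 2.0,
):
    """Bead discretization of the model geometry.

    Each component is tiled with its own z-layer grid so slab boundaries are
    honoured exactly (the in-plane lattice is shared).  Returns (positions
    (n, 3) in A, role array with entries in {'lipid-tail', 'lipid-head',
    'belt'}, per-bead volume array).  Bead volumes are normalized per
    component so each component's total volume is exact, which pins the
    forward scattering; the residual discretization error is the boundary
    jaggedness, controlled by ``spacing``.
    """
    if spacing > 3.0:
        raise ValueError("bead spacing > 3 A is too coarse for q <= 0.25 1/A")
    comp = composition if composition is not None else MolecularComposition()
    dims = derive_dimensions(params, comp)
    a, b, w = dims.r_major, dims.r_minor, dims.w_belt
    xy_core, wt_core = _ellipse_cells(a, b, spacing)
    xy_belt, wt_belt = _annulus_cells(a, b, w, spacing)

    v_tail = math.pi * a * b * dims.h_tails
    v_head = math.pi * a * b * 2.0 * dims.d_head
    v_belt = 2.0 * params.cv_belt * comp.belt.volume

    pos_parts, role_parts, vol_parts = [], [], []

    def add(xy_pts, xy_wts, z_centers, role, v_total):
        nz = len(z_centers)
        P = np.column_stack([
            np.repeat(xy_pts, nz, axis=0),
            np.tile(z_centers, len(xy_pts)),
        ])
        pos_parts.append(P)
        role_parts.append(np.full(len(P), role, dtype="U10"))
        vol_parts.append(np.repeat(xy_wts, nz) * (v_total / nz))

    add(xy_core, wt_core, _z_layers(-dims.h_tails / 2, dims.h_tails / 2, spacing),
        "lipid-tail", v_tail)
    z_head = np.concatenate([
        _z_layers(dims.h_tails / 2, dims.h_lipid / 2, spacing),
        _z_layers(-dims.h_lipid / 2, -dims.h_tails / 2, spacing),
    ])
    add(xy_core, wt_core, z_head, "lipid-head", v_head)
    add(xy_belt, wt_belt, _z_layers(-params.h_belt / 2, params.h_belt / 2, spacing),
        "belt", v_belt)
    return (np.vstack(pos_parts), np.concatenate(role_parts),
            np.concatenate(vol_parts))


_ROLE_TO_COMPONENT = {"lipid-tail": "tails", "lipid-head": "head", "belt": "belt",
                      "tag": "tag"}


def bead_scattering_lengths(roles, slds: ContrastSet, bead_volume) -> np.ndarray:
    """Excess scattering length per bead (fm): drho(role) * v_bead."""
    drho = np.array([slds[_ROLE_TO_COMPONENT[r]] for r in roles])
    return drho * np.asarray(bead_volume)


def model_pr(
    params: NanodiscParams,
    composition: MolecularComposition | None = None,
    contrast: str = "xray",
    r_grid=None,
    spacing: float = 2.0,
):
    """Pair-distance distribution p(r) of the model via bead discretization.

    p(r) is the histogram of pairwise bead distances weighted by products of
    excess bead scattering lengths; it vanishes beyond
    D_max = sqrt((2(a + W))^2 + H_lipid^2).
    """
    comp = composition if composition is not None else MolecularComposition()
    solvent = "h2o" if contrast == "xray" else "d2o"
    slds = component_slds(comp, contrast, solvent)
    dims = derive_dimensions(params, comp)
    pos, roles, v_bead = discretize_model(params, comp, spacing)
    bvals = bead_scattering_lengths(roles, slds, v_bead)
    d_max = math.hypot(2 * (dims.r_major + dims.w_belt), dims.h_lipid) + spacing
    if r_grid is None:
        r_grid = np.linspace(0.0, d_max, 201)
    r_grid = np.asarray(r_grid, dtype=float)
    edges = np.concatenate([r_grid - 0.5 * np.gradient(r_grid), [r_grid[-1] + 0.5 * (r_grid[-1] - r_grid[-2])]])
    hist = np.zeros(len(r_grid))
    chunk = 400
    n = len(pos)
    for i0 in range(0, n, chunk):
        block = pos[i0 : i0 + chunk]
        d = np.sqrt(((block[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        wgt = bvals[i0 : i0 + chunk, None] * bvals[None, :]
        iu = np.arange(i0, i0 + len(block))[:, None] < np.arange(n)[None, :]
        h, _ = np.histogram(d[iu], bins=edges, weights=wgt[iu])
        hist += h
    return r_grid, hist


def pr_to_intensity(r_grid, pr, qgrid, self_term: float = 0.0) -> np.ndarray:
    """Numeric transform I(q) = 2 * sum_r p(r) sinc(q r) + self term."""
    q = np.asarray(qgrid, dtype=float)
    s = np.sinc(np.outer(q, r_grid) / math.pi)
    return 2.0 * s @ pr + self_term
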