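"""Debye-equation scattering from coarse-grained bead conformations.

For an ensemble of frames with per-bead excess scattering lengths db (fm),

    I(q) = sum_j w_j [ sum_k db_k^2 + 2 sum_{k<l} db_k db_l sinc(q d_kl) ]

evaluated with a pair-distance histogram (default bin 0.25 A) so the cost per
frame is O(n_beads^2) distances but O(n_bins) per q point.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist

from .curves import ScatteringCurve


def pair_histogram(pos: np.ndarray, b: np.ndarray, bin_width: float = 0.25,
                   chunk: int = 1024):
    """Weighted pair-distance histogram: bin centers and sum of b_k*b_l per bin."""
    n = len(pos)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    d_max = float(np.linalg.norm(hi - lo)) + bin_width
    n_bins = max(1, int(math.ceil(d_max / bin_width)))
    hist = np.zeros(n_bins + 2)
    inv = 1.0 / bin_width

    def deposit(d, w):
        # linear (cloud-in-cell) deposit between the two nearest bin centers
        x = np.clip(d * inv - 0.5, 0.0, n_bins)
        lo = x.astype(np.intp)
        frac = x - lo
        np.add.at(hist, lo, w * (1.0 - frac))
        np.add.at(hist, lo + 1, w * frac)

    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        # only pairs (k, l) with k < l: rows i0..i1 against columns > row index
        d = cdist(pos[i0:i1], pos[i1:])
        deposit(d.ravel(), np.outer(b[i0:i1], b[i1:]).ravel())
        if i1 - i0 > 1:
            dblk = cdist(pos[i0:i1], pos[i0:i1])
            iu = np.triu_indices(i1 - i0, k=1)
            deposit(dblk[iu], b[i0:i1][iu[0]] * b[i0:i1][iu[1]])
    centers = (np.arange(n_bins + 2) + 0.5) * bin_width
    return centers, hist


def frame_intensity(pos: np.ndarray, b: np.ndarray, qgrid, bin_width: float = 0.25,
                    exact: bool = False) -> np.ndarray:
    """Debye intensity of a single frame (fm^2)."""
    pos = np.asarray(pos, dtype=float)
    b = np.asarray(b, dtype=float)
    if pos.ndim != 2 or pos.shape[0] == 0:
        raise ValueError("frame must contain at least one bead")
    q = np.asarray(qgrid, dtype=float)
    self_term = float((b**2).sum())
    if len(pos) == 1:
        return np.full(len(q), self_term)
    if exact:
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(pos), k=1)
        dv, wv = d[iu], (b[:, None] * b[None, :])[iu]
        return self_term + 2.0 * np.sinc(np.outer(q, dv) / math.pi) @ wv
    centers, hist = pair_histogram(pos, b, bin_width)
    nz = hist != 0
    return self_term + 2.0 * np.sinc(np.outer(q, centers[nz]) / math.pi) @ hist[nz]


def debye_intensity(
    frames,
    bead_b,
    weights,
    qgrid,
    bin_width: float = 0.25,
    scale: float = 1.0,
    exact: bool = False,
) -> ScatteringCurve:
    """Weighted ensemble Debye intensity.

    ``frames`` is a sequence of (n_beads, 3) arrays; ``bead_b`` either one
    shared per-bead excess scattering-length array or one per frame.
    """
    w = np.asarray(weights, dtype=float)
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    q = np.asarray(qgrid, dtype=float)
    shared_b = isinstance(bead_b, np.ndarray) and bead_b.ndim == 1
    acc = np.zeros(len(q))
    for j, pos in enumerate(frames):
        if w[j] == 0.0:
            continue
        b = bead_b if shared_b else np.asarray(bead_b[j], dtype=float)
        acc += w[j] * frame_intensity(pos, b, q, bin_width, exact=exact)
    return ScatteringCurve(q=q, intensity=scale * acc, sigma=np.ones(len(q)),
                           label="debye")
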