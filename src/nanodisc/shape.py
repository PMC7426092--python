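"""Ensemble shape analysis: gyration tensor, acylindricity, QT clustering.

Acylindricity quantifies how far a disc cross-section deviates from circular.
Two conventions are exposed deliberately:

* ``acylindricity_coords`` works on coordinates through the gyration tensor,
  C = sqrt(lx^2 - ly^2), where lx^2 >= ly^2 are the two in-plane principal
  moments (the bilayer normal carries the smallest moment and is labelled z).
* ``acylindricity_axes`` works on fitted ellipse semi-axes,
  C = sqrt(a^2 - b^2).

For a parameter-uniform elliptical ring the two differ by exactly sqrt(2)
(ring second moments are a^2/2 and b^2/2), which is why both are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def gyration_eigs(coords: np.ndarray):
    """Eigenvalues (descending) and axes of the uniform-mass gyration tensor.

    Returns (eigenvalues [lx2, ly2, lz2], axes as columns).  The smallest
    eigenvalue corresponds to the bilayer normal for disc-like bodies.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    c = x - x.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set")
    tensor = c.T @ c / len(c)
    vals, vecs = np.linalg.eigh(tensor)  # ascending
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def acylindricity_coords(coords: np.ndarray) -> float:
    """C = sqrt(lx^2 - ly^2) from the two largest gyration-tensor moments, A."""
    if len(np.asarray(coords)) == 0:
        raise ValueError("empty selection")
    vals, _ = gyration_eigs(coords)
    return float(np.sqrt(max(vals[0] - vals[1], 0.0)))


def acylindricity_axes(r_major: float, r_minor: float) -> float:
    """C = sqrt(a^2 - b^2) from fitted ellipse semi-axes, A."""
    if not (r_major >= r_minor > 0):
        raise ValueError("require r_major >= r_minor > 0")
    return float(np.sqrt(r_major**2 - r_minor**2))


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD after optimal superposition (Kabsch, uniform masses), A."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    s = s * np.array([1.0, 1.0, d])
    msd = max((xc**2).sum() + (yc**2).sum() - 2.0 * s.sum(), 0.0) / len(x)
    return float(np.sqrt(msd))


def pairwise_rmsd(frames) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over coordinate blocks."""
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(frames[i], frames[j])
    return mat


@dataclass
class Clustering:
    labels: np.ndarray  # cluster id per frame, committed order (0 = largest first)
    medoids: list[int]
    cutoff: float
    audit: list[dict] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def qt_cluster(frames, cutoff: float = 5.8, rmsd_matrix: np.ndarray | None = None
               ) -> Clustering:
    """Quality-Threshold clustering on pairwise superposed RMSD.

    Iteratively: every unassigned frame proposes a candidate cluster (itself
    plus all unassigned frames within ``cutoff`` RMSD of it); the largest
    candidate is committed; ties break toward the lowest seed index.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("at least one frame required")
    dmat = pairwise_rmsd(frames) if rmsd_matrix is None else np.asarray(rmsd_matrix)
    labels = np.full(n, -1, dtype=int)
    audit = []
    medoids: list[int] = []
    k = 0
    while np.any(labels == -1):
        unassigned = np.flatnonzero(labels == -1)
        best_seed, best_members = None, None
        for seed in unassigned:
            members = unassigned[dmat[seed, unassigned] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_seed, best_members = seed, members
        labels[best_members] = k
        sub = dmat[np.ix_(best_members, best_members)]
        medoids.append(int(best_members[np.argmin(sub.sum(axis=1))]))
        audit.append({"step": k, "seed": int(best_seed),
                      "size": int(len(best_members)),
                      "members": best_members.tolist()})
        k += 1
    return Clustering(labels=labels, medoids=medoids, cutoff=cutoff, audit=audit)


def cluster_populations(
    clustering: Clustering,
    prior_weights,
    posterior_weights=None,
    acylindricity=None,
) -> pd.DataFrame:
    """Per-cluster weights before/after reweighting and mean acylindricity."""
    w0 = np.asarray(prior_weights, dtype=float)
    w0 = w0 / w0.sum()
    w1 = w0 if posterior_weights is None else np.asarray(posterior_weights, float)
    w1 = w1 / w1.sum()
    rows = []
    for kc in range(clustering.n_clusters):
        idx = clustering.members(kc)
        row = {
            "cluster": kc,
            "size": len(idx),
            "prior": float(w0[idx].sum()),
            "posterior": float(w1[idx].sum()),
        }
        if acylindricity is not None:
            cvals = np.asarray(acylindricity, dtype=float)[idx]
            row["mean_C_prior"] = float((w0[idx] / w0[idx].sum()) @ cvals)
            row["mean_C_posterior"] = float((w1[idx] / max(w1[idx].sum(), 1e-300)) @ cvals)
        rows.append(row)
    return pd.DataFrame(rows)
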