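"""Bayesian / Maximum-Entropy (BME) ensemble reweighting.

Given per-frame observables F_i(x_j), experimental values F_i^EXP with
uncertainties sigma_i, and prior frame weights w0, the method minimizes

    L(w) = (m/2) chi2_r(w) - theta * S_rel(w)

where chi2_r = (1/m) sum_i (<F_i>_w - F_i^EXP)^2 / sigma_i^2 and
S_rel = -sum_j w_j log(w_j / w0_j) <= 0.  The hyperparameter theta balances
goodness of fit against perturbation of the prior; phi_eff = exp(S_rel) is
the effective fraction of frames retained.

The primal problem is solved through its convex dual over Lagrange
multipliers lambda_i (one per observable),

    Gamma(lambda) = log Z(lambda) + sum_i lambda_i F_i^EXP
                    + (theta/2) sum_i lambda_i^2 sigma_i^2,
    w_j(lambda) proportional to w0_j exp(-sum_i lambda_i F_i(x_j)),

with sign constraints for one-sided restraints: an upper bound on <F_i>
admits only lambda_i >= 0, a lower bound only lambda_i <= 0.  At the optimum
L(w*) = -theta * Gamma(lambda*), which provides a dual/primal consistency
check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

KINDS = ("equality", "upper_bound", "lower_bound")


@dataclass
class ObservableSet:
    """Per-frame observable matrix with experimental targets.

    ``F`` has shape (m, n): m observables (rows) by n ensemble frames.
    ``kind`` is a single restraint kind for the whole set or one per row.
    """

    F: np.ndarray
    F_exp: np.ndarray
    sigma: np.ndarray
    kind: str | np.ndarray = "equality"
    label: str = ""

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.F_exp = np.asarray(self.F_exp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        m = self.F.shape[0]
        if self.F_exp.shape != (m,) or self.sigma.shape != (m,):
            raise ValueError("F_exp and sigma must have one entry per observable row")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if isinstance(self.kind, str):
            if self.kind not in KINDS:
                raise ValueError(f"unknown restraint kind {self.kind!r}")
            self.kind = np.full(m, self.kind, dtype=object)
        else:
            self.kind = np.asarray(self.kind, dtype=object)
            if self.kind.shape != (m,):
                raise ValueError("kind must be scalar or one per row")

    @property
    def m(self) -> int:
        return self.F.shape[0]

    @property
    def n(self) -> int:
        return self.F.shape[1]


def chi2_reduced(weights, obs: ObservableSet) -> float:
    """Reduced chi-square of the weighted ensemble against one observable set.

    One-sided kinds contribute only when the bound is violated: an upper
    bound when <F> exceeds F_exp, a lower bound when <F> falls below it.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (obs.n,):
        raise ValueError("weights length must equal the ensemble size")
    avg = obs.F @ w
    dev = avg - obs.F_exp
    upper = obs.kind == "upper_bound"
    lower = obs.kind == "lower_bound"
    dev = np.where(upper & (dev < 0), 0.0, dev)
    dev = np.where(lower & (dev > 0), 0.0, dev)
    return float(((dev / obs.sigma) ** 2).mean())


def rel_entropy(weights, ref_weights) -> float:
    """S_rel = -sum_j w_j log(w_j / w0_j) <= 0, with 0 log 0 = 0."""
    w = np.asarray(weights, dtype=float)
    w0 = np.asarray(ref_weights, dtype=float)
    if np.any((w > 0) & (w0 <= 0)):
        raise ValueError("weights must be absolutely continuous w.r.t. reference")
    nz = w > 0
    return float(-(w[nz] * np.log(w[nz] / w0[nz])).sum())


def phi_eff(weights, ref_weights) -> float:
    """Effective ensemble fraction exp(S_rel), in (0, 1]."""
    return float(np.exp(rel_entropy(weights, ref_weights)))


@dataclass
class ReweightResult:
    weights: np.ndarray
    theta: float
    lambdas: np.ndarray
    chi2_before: dict
    chi2_after: dict
    s_rel: float
    phi: float
    primal_value: float
    dual_value: float
    converged: bool
    grad_norm: float
    diagnostics: dict = field(default_factory=dict)


def _stack(obs_sets):
    F = np.vstack([o.F for o in obs_sets])
    F_exp = np.concatenate([o.F_exp for o in obs_sets])
    sigma = np.concatenate([o.sigma for o in obs_sets])
    kind = np.concatenate([o.kind for o in obs_sets])
    return F, F_exp, sigma, kind


def maxent_reweight(
    obs: ObservableSet | list[ObservableSet],
    theta: float,
    ref_weights,
    lambda0: np.ndarray | None = None,
    gtol: float = 1e-10,
) -> ReweightResult:
    """Solve the BME problem for one theta; multiple sets share the theta.

    Deterministic: the dual is convex and solved by L-BFGS-B with analytic
    gradient from a fixed start (zeros unless ``lambda0`` warm-starts it).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    obs_sets = [obs] if isinstance(obs, ObservableSet) else list(obs)
    w0 = np.asarray(ref_weights, dtype=float)
    w0 = w0 / w0.sum()
    if np.any(w0 <= 0):
        raise ValueError("reference weights must be strictly positive")
    F, F_exp, sigma, kind = _stack(obs_sets)
    if F.shape[1] != len(w0):
        raise ValueError("observable matrices and weights disagree on ensemble size")
    # Standardized parametrization mu_i = lambda_i * sigma_i with rows
    # G'_i = (F_i - F_exp_i) / sigma_i: same optimum, and the dual gradient
    # becomes O(1) (units of standardized deviations), making the
    # convergence threshold scale-free.
    G = (F - F_exp[:, None]) / sigma[:, None]
    log_w0 = np.log(w0)

    def weights_of(mu):
        logits = log_w0 - mu @ G
        return np.exp(logits - logsumexp(logits))

    def dual(mu):
        logits = log_w0 - mu @ G
        val = logsumexp(logits) + 0.5 * theta * (mu @ mu)
        w = np.exp(logits - logsumexp(logits))
        grad = -(G @ w) + theta * mu
        return val, grad

    bounds = []
    for k in kind:
        if k == "upper_bound":
            bounds.append((0.0, None))
        elif k == "lower_bound":
            bounds.append((None, 0.0))
        else:
            bounds.append((None, None))
    x0 = (np.zeros(F.shape[0]) if lambda0 is None
          else np.asarray(lambda0, dtype=float) * sigma)
    res = minimize(
        dual, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "maxfun": 50000, "ftol": 1e-16, "gtol": gtol},
    )
    mu = res.x
    w = weights_of(mu)
    lam = mu / sigma
    # projected gradient norm (bound-respecting measure of convergence)
    _, g = dual(mu)
    pg = g.copy()
    for i, k in enumerate(kind):
        if k == "upper_bound" and mu[i] <= 0 and g[i] > 0:
            pg[i] = 0.0
        if k == "lower_bound" and mu[i] >= 0 and g[i] < 0:
            pg[i] = 0.0
    grad_norm = float(np.abs(pg).max()) if len(pg) else 0.0

    s_rel = rel_entropy(w, w0)
    chi2_b = {o.label or i: chi2_reduced(w0, o) for i, o in enumerate(obs_sets)}
    chi2_a = {o.label or i: chi2_reduced(w, o) for i, o in enumerate(obs_sets)}
    primal = sum(0.5 * o.m * chi2_reduced(w, o) for o in obs_sets) - theta * s_rel
    dual_val = -theta * res.fun
    return ReweightResult(
        weights=w,
        theta=theta,
        lambdas=lam,
        chi2_before=chi2_b,
        chi2_after=chi2_a,
        s_rel=s_rel,
        phi=float(np.exp(s_rel)),
        primal_value=float(primal),
        dual_value=float(dual_val),
        converged=bool(res.success) and grad_norm < 1e-6,
        grad_norm=grad_norm,
        diagnostics={"n_iter": res.nit, "message": str(res.message)},
    )


def write_observables(obs: ObservableSet, path) -> None:
    """TSV: one observable per row; F_exp, sigma, kind, then frame columns."""
    with open(path, "w") as fh:
        cols = "\t".join(f"frame{j}" for j in range(obs.n))
        fh.write(f"# label = {obs.label}\n")
        fh.write(f"F_exp\tsigma\tkind\t{cols}\n")
        for i in range(obs.m):
            vals = "\t".join(f"{v:.10e}" for v in obs.F[i])
            fh.write(f"{obs.F_exp[i]:.10e}\t{obs.sigma[i]:.10e}\t{obs.kind[i]}\t{vals}\n")


def read_observables(path) -> ObservableSet:
    label = ""
    rows, fe, sg, kd = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# label"):
                label = line.partition("=")[2].strip()
                continue
            if not line or line.startswith("#") or line.startswith("F_exp"):
                continue
            parts = line.split("\t")
            fe.append(float(parts[0]))
            sg.append(float(parts[1]))
            kd.append(parts[2])
            rows.append([float(v) for v in parts[3:]])
    return ObservableSet(F=np.array(rows), F_exp=np.array(fe), sigma=np.array(sg),
                         kind=np.array(kd, dtype=object), label=label)


def theta_scan(
    obs: ObservableSet | list[ObservableSet],
    ref_weights,
    theta_grid=None,
) -> pd.DataFrame:
    """Reweight along a decreasing theta grid and tabulate the L-curve.

    Returns a table of (theta, chi2 per set, aggregate chi2, S_rel, phi_eff)
    with a boolean ``elbow`` column marking the suggested theta (maximum
    distance from the chord of the normalized chi2-vs-(-S_rel) curve).  The
    final choice of theta is left to the user.
    """
    obs_sets = [obs] if isinstance(obs, ObservableSet) else list(obs)
    if theta_grid is None:
        theta_grid = np.geomspace(1000.0, 0.1, 20)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if np.any(np.diff(theta_grid) >= 0):
        raise ValueError("theta grid must be decreasing")
    rows = []
    lam = None
    results = []
    m_tot = sum(o.m for o in obs_sets)
    for th in theta_grid:
        r = maxent_reweight(obs_sets, th, ref_weights, lambda0=lam)
        lam = r.lambdas
        agg = sum(o.m * r.chi2_after[o.label or i]
                  for i, o in enumerate(obs_sets)) / m_tot
        row = {"theta": th, "chi2": agg, "s_rel": r.s_rel, "phi_eff": r.phi}
        for i, o in enumerate(obs_sets):
            row[f"chi2_{o.label or i}"] = r.chi2_after[o.label or i]
        rows.append(row)
        results.append(r)
    table = pd.DataFrame(rows)
    x = -table["s_rel"].to_numpy()
    y = table["chi2"].to_numpy()
    span_x = max(x.max() - x.min(), 1e-12)
    span_y = max(y.max() - y.min(), 1e-12)
    xn, yn = (x - x.min()) / span_x, (y - y.min()) / span_y
    # distance from the chord joining the path endpoints (kneedle criterion)
    dx, dy = xn[-1] - xn[0], yn[-1] - yn[0]
    dist = np.abs(dy * xn - dx * yn + dx * yn[0] - dy * xn[0]) / np.hypot(dx, dy)
    table["elbow"] = False
    table.loc[int(np.argmax(dist)), "elbow"] = True
    table.attrs["results"] = results
    return table
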