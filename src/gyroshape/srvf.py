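"""Square-root velocity transform and elastic pairwise alignment.

The SRVF of a curve beta is q = sign(beta') * sqrt(|beta'|).  Under a time
warp gamma the SRVF transforms as (q o gamma) * sqrt(gamma'), an isometry of
L2, so the optimal warp aligning beta2 to beta1 solves

    argmin_gamma || q1 - (q2 o gamma) sqrt(gamma') ||

and the attained minimum is the amplitude (shape) distance d_a, invariant to
time warps of either input.  The minimization is carried out by dynamic
programming over monotone lattice paths with local slopes p/q, 1 <= p, q <= 3.
"""

from __future__ import annotations

import numpy as np

from .curves import (
    AlignmentResult,
    GridError,
    SrvfCurve,
    Trajectory,
    WarpingFunction,
)

__all__ = [
    "to_srvf",
    "from_srvf",
    "warp_trajectory",
    "warp_srvf",
    "l2_norm",
    "pairwise_align",
    "amplitude_distance",
    "DP_STEPS",
]

# Allowed local slopes dj/di; diagonal first so exact ties resolve to the
# least-warped path.  Non-coprime pairs are redundant with (1, 1).
DP_STEPS: tuple[tuple[int, int], ...] = (
    (1, 1),
    (1, 2),
    (2, 1),
    (2, 3),
    (3, 2),
    (1, 3),
    (3, 1),
)


def _derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Centered differences in the interior, one-sided at the endpoints."""
    return np.gradient(values, dt)


def _smooth(values: np.ndarray, window: int = 7) -> np.ndarray:
    w = np.hanning(window)
    w /= w.sum()
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, w, mode="valid")


def to_srvf(curve: Trajectory, presmooth: bool = False) -> SrvfCurve:
    """SRVF transform q = sign(beta') sqrt(|beta'|).

    Parameters
    ----------
    curve : trajectory on a uniform grid.
    presmooth : apply a short Hann window to the values before differencing
        (off by default; useful for rough sensor traces).
    """
    vals = _smooth(curve.values) if presmooth else curve.values
    deriv = _derivative(vals, curve.dt)
    q = np.sign(deriv) * np.sqrt(np.abs(deriv))
    return SrvfCurve(curve.grid, q, origin_value=float(curve.values[0]))


def from_srvf(srvf: SrvfCurve, **traj_kwargs) -> Trajectory:
    """Invert the SRVF map: beta(t) = beta(0) + int_0^t sign(q) q^2."""
    integrand = np.sign(srvf.values) * srvf.values**2
    beta = np.concatenate(
        [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) * 0.5 * srvf.dt)]
    )
    return Trajectory(srvf.grid, srvf.origin_value + beta, **traj_kwargs)


def warp_trajectory(curve: Trajectory, gamma: WarpingFunction) -> Trajectory:
    """Time warp beta o gamma by linear interpolation onto the common grid."""
    if curve.grid.shape != gamma.grid.shape:
        raise GridError("trajectory and warp must share a grid")
    warped = np.interp(gamma.values, curve.grid, curve.values)
    return Trajectory(
        curve.grid, warped,
        subject_id=curve.subject_id, visit=curve.visit, activity=curve.activity,
    )


def warp_srvf(q: SrvfCurve, gamma: WarpingFunction) -> SrvfCurve:
    """Group action (q o gamma) * sqrt(gamma'); preserves the L2 norm of q."""
    if q.grid.shape != gamma.grid.shape:
        raise GridError("SRVF and warp must share a grid")
    gdot = np.gradient(gamma.values, q.dt)
    gdot = np.maximum(gdot, 0.0)
    warped = np.interp(gamma.values, q.grid, q.values) * np.sqrt(gdot)
    return SrvfCurve(q.grid, warped, origin_value=q.origin_value)


def l2_norm(values: np.ndarray, grid: np.ndarray) -> float:
    """Discrete L2 norm sqrt((T/J) * sum f(t_j)^2) on a uniform grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    T = grid[-1] - grid[0]
    J = values.size
    return float(np.sqrt(T / J * np.sum(values**2)))


def _segment_cost_tables(q1: np.ndarray, q2: np.ndarray, dt: float) -> list[np.ndarray]:
    """Per-step tables C[s][i, j] = cost of the lattice segment leaving (i, j).

    A segment from (i, j) to (i+di, j+dj) carries gamma linear with slope
    s = dj/di; its cost is the trapezoid approximation of
    int (q1(t) - q2(gamma(t)) sqrt(s))^2 dt over the di subintervals.
    """
    M = q1.size
    idx = np.arange(M, dtype=float)
    tables = []
    for di, dj in DP_STEPS:
        s = dj / di
        root_s = np.sqrt(s)
        ni, nj = M - di, M - dj
        C = np.zeros((ni, nj))
        for k in range(di + 1):
            w = 0.5 if k in (0, di) else 1.0
            q1k = q1[k : k + ni]                      # q1 at i + k, i = 0..ni-1
            pos = idx[:nj] + k * s                    # fractional index j + k*s
            q2k = np.interp(pos, idx, q2)
            diff = q1k[:, None] - root_s * q2k[None, :]
            C += w * diff * diff
        tables.append(C * dt)
    return tables


def _hann_smooth_warp(values: np.ndarray, T: float, window: int) -> np.ndarray:
    """Boundary-pinned monotone Hann smoothing of warp samples."""
    if window < 3:
        return values
    w = np.hanning(window)
    w /= w.sum()
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect", reflect_type="odd")
    sm = np.convolve(padded, w, mode="valid")
    sm[0], sm[-1] = 0.0, T
    return np.maximum.accumulate(sm)


def _polish_warp(
    q1v: np.ndarray,
    q2v: np.ndarray,
    grid: np.ndarray,
    gamma0: np.ndarray,
    n_knots: int = 20,
    maxiter: int = 150,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Local refinement of a warp by quasi-Newton descent on log gamma'.

    The warp is parametrized by log-derivative values at ``n_knots`` uniform
    knots (linearly interpolated, exponentiated, integrated and renormalized
    to pin the endpoints), which keeps every iterate a valid diffeomorphism.
    Started from the (smoothed) DP path, this removes the slope-quantization
    noise of the lattice.  Returns (gamma, gamma', attained misfit).
    """
    from scipy.optimize import minimize

    T = grid[-1]
    dt = grid[1] - grid[0]
    knots = np.linspace(0.0, T, n_knots)
    gd0 = np.clip(np.gradient(gamma0, dt), 1e-3, None)
    z0 = np.clip(np.log(np.interp(knots, grid, gd0)), -6.0, 6.0)

    def gamma_from(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        v = np.exp(np.interp(grid, knots, z))
        G = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) * 0.5 * dt)])
        G *= T / G[-1]
        return G, np.clip(np.gradient(G, dt), 0.0, None)

    def objective(z: np.ndarray) -> float:
        G, gd = gamma_from(z)
        aligned = np.interp(G, grid, q2v) * np.sqrt(gd)
        d = q1v - aligned
        return dt * float(np.sum(d * d))

    res = minimize(objective, z0, method="L-BFGS-B",
                   bounds=[(-6.0, 6.0)] * n_knots, options={"maxiter": maxiter})
    z_best = res.x if res.fun <= objective(z0) else z0
    G, gd = gamma_from(z_best)
    return G, gd, float(np.sqrt(min(res.fun, objective(z0))))


def pairwise_align(
    q1: SrvfCurve,
    q2: SrvfCurve,
    polish: bool = True,
    smooth_window: int = 15,
) -> AlignmentResult:
    """Optimal elastic alignment of curve 2 to curve 1.

    Dynamic programming over monotone lattice paths (slopes from
    ``DP_STEPS``) finds the global minimizer on the lattice; exact cost ties
    prefer the path closer to the diagonal.  With ``polish`` (default) the
    lattice path is then smoothed and refined by a local descent in a smooth
    warp family, which removes the lattice's slope-quantization noise; the
    reported ``distance`` is the misfit attained by the returned warp, and
    the raw lattice optimum is kept in ``dp_cost``.
    """
    if q1.grid.shape != q2.grid.shape:
        raise GridError("SRVFs must share a grid length for alignment")
    M = q1.grid.size
    dt = q1.dt
    C = _segment_cost_tables(q1.values, q2.values, dt)

    INF = np.inf
    E = np.full((M, M), INF)
    P = np.full((M, M), -1, dtype=np.int8)
    E[0, 0] = 0.0
    for i in range(1, M):
        for s, (di, dj) in enumerate(DP_STEPS):
            if di > i:
                continue
            # candidate costs for targets j = dj .. M-1
            cand = E[i - di, : M - dj] + C[s][i - di, : M - dj]
            row = E[i, dj:]
            better = cand < row
            row[better] = cand[better]
            P[i, dj:][better] = s
    # backtrack the optimal path
    path_i, path_j = [M - 1], [M - 1]
    i = j = M - 1
    while i > 0:
        di, dj = DP_STEPS[P[i, j]]
        i -= di
        j -= dj
        path_i.append(i)
        path_j.append(j)
    path_i.reverse()
    path_j.reverse()

    gamma_vals = np.interp(np.arange(M, dtype=float), np.array(path_i, dtype=float),
                           q1.grid[np.array(path_j)])
    dp_cost = float(np.sqrt(E[M - 1, M - 1]))

    if polish:
        smoothed = _hann_smooth_warp(gamma_vals, q1.T, smooth_window)
        G, gd, distance = _polish_warp(q1.values, q2.values, q1.grid, smoothed)
        if distance > dp_cost:  # retry from the raw lattice path
            G2, gd2, d2 = _polish_warp(q1.values, q2.values, q1.grid, gamma_vals)
            if d2 < distance:
                G, gd, distance = G2, gd2, d2
        warp = WarpingFunction(q1.grid, G)
        aligned_vals = np.interp(G, q1.grid, q2.values) * np.sqrt(gd)
        aligned_q = SrvfCurve(q1.grid, aligned_vals, origin_value=q2.origin_value)
    else:
        warp = WarpingFunction(q1.grid, gamma_vals)
        distance = dp_cost
        aligned_q = warp_srvf(q2, warp)
    aligned_curve = from_srvf(aligned_q)
    result = AlignmentResult(
        warp=warp, distance=distance, aligned_curve=aligned_curve, aligned_srvf=aligned_q
    )
    result.dp_cost = dp_cost
    return result


def amplitude_distance(
    beta1: Trajectory, beta2: Trajectory, polish: bool = True, symmetrize: bool = True
) -> float:
    """Amplitude (shape) distance d_a: the minimal SRVF misfit over warps.

    The underlying quantity is symmetric; each alignment direction yields an
    upper bound on it, so by default the smaller of the two is returned,
    which stabilizes the estimate against local-refinement noise.  Set
    ``symmetrize=False`` for the plain one-directional evaluation.
    """
    q1, q2 = to_srvf(beta1), to_srvf(beta2)
    d12 = pairwise_align(q1, q2, polish=polish).distance
    if not symmetrize:
        return d12
    d21 = pairwise_align(q2, q1, polish=polish).distance
    return min(d12, d21)
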