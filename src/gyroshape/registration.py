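"""Multiple curve alignment: Karcher mean and phase-amplitude separation.

The mean shape of an ensemble {beta_i} is the SRVF mu minimizing the summed
squared elastic distances

    sum_i min_gamma || mu - (q_i o gamma) sqrt(gamma') ||^2 ,

found by alternating (1) elastic alignment of every SRVF to the current mean
and (2) replacement of the mean by the cross-sectional average of the aligned
SRVFs.  Each curve then decomposes into an amplitude (the aligned curve) and
a phase (the warp that reconstructs the original): beta_i = amp_i o phase_i.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import AlignmentResult, GridError, SrvfCurve, Trajectory, WarpingFunction
from .srvf import from_srvf, l2_norm, pairwise_align, to_srvf, warp_srvf, warp_trajectory

__all__ = [
    "SeparationResult",
    "karcher_mean",
    "separate_phase_amplitude",
    "align_to_reference",
    "euclidean_mean",
]

logger = logging.getLogger(__name__)


@dataclass
class SeparationResult:
    """Output of phase-amplitude separation on an ensemble of curves.

    ``phases[i]`` is the warp gamma_i* with ``amplitudes[i] o gamma_i*``
    reconstructing input curve i; ``mean_srvf`` is the Karcher mean shape.
    """

    mean_srvf: SrvfCurve
    mean_trajectory: Trajectory
    phases: list[WarpingFunction]
    amplitudes: list[Trajectory]
    aligned_srvfs: list[SrvfCurve]
    iterations: int
    converged: bool

    def save(self, out_dir: str | Path) -> None:
        """Serialize to a directory: mean CSV, phases/amplitudes CSVs, metadata JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid = self.mean_trajectory.grid
        pd.DataFrame({"t": grid, "mean": self.mean_trajectory.values}).to_csv(
            out / "mean.csv", index=False
        )
        ph = pd.DataFrame({"t": grid})
        am = pd.DataFrame({"t": grid})
        for i, (p, a) in enumerate(zip(self.phases, self.amplitudes)):
            key = a.subject_id or str(i)
            ph[f"phase_{key}_{a.visit}"] = p.values
            am[f"amp_{key}_{a.visit}"] = a.values
        ph.to_csv(out / "phases.csv", index=False)
        am.to_csv(out / "amplitudes.csv", index=False)
        (out / "metadata.json").write_text(
            json.dumps({"iterations": self.iterations, "converged": self.converged,
                        "n_curves": len(self.amplitudes)})
        )


def euclidean_mean(curves: list[Trajectory]) -> Trajectory:
    """Pointwise cross-sectional average; the naive contrast to the shape mean."""
    _require_common_grid(curves)
    vals = np.mean([c.values for c in curves], axis=0)
    return Trajectory(curves[0].grid, vals, activity=curves[0].activity)


def _require_common_grid(curves: list[Trajectory | SrvfCurve]) -> None:
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    g0 = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != g0.shape or not np.allclose(c.grid, g0):
            raise GridError("curves must share a common grid")


def karcher_mean(
    curves: list[Trajectory],
    tol: float = 1e-4,
    max_iter: int = 20,
    center_phases: bool = True,
    polish_final: bool = True,
) -> SeparationResult:
    """Karcher (Frechet) mean of the curves' SRVFs with phase-amplitude output.

    Parameters
    ----------
    curves : >= 2 trajectories on a common grid.
    tol : stop when the relative L2 change of the mean falls below this.
    max_iter : iteration cap; non-convergence is reported, never raised.
    center_phases : re-center warps so their pointwise mean is the identity,
        re-warping the mean shape accordingly.
    polish_final : refine the final per-curve warps beyond the DP lattice
        (slower but more accurate phases/amplitudes); mean updates always use
        the fast lattice alignment.
    """
    if len(curves) < 2:
        raise ValueError("karcher_mean needs at least 2 curves")
    _require_common_grid(curves)
    grid = curves[0].grid
    qs = [to_srvf(c) for c in curves]
    Q = np.stack([q.values for q in qs])

    # init: the input SRVF closest in L2 to the cross-sectional average
    qbar = Q.mean(axis=0)
    start = int(np.argmin([l2_norm(q - qbar, grid) for q in Q]))
    mu = Q[start].copy()

    converged = False
    iterations = 0
    aligned = Q.copy()
    warps: list[WarpingFunction] = [WarpingFunction.identity(grid) for _ in qs]
    for iterations in range(1, max_iter + 1):
        mu_curve = SrvfCurve(grid, mu)
        results = [pairwise_align(mu_curve, q, polish=False) for q in qs]
        warps = [r.warp for r in results]
        aligned = np.stack([r.aligned_srvf.values for r in results])
        mu_new = aligned.mean(axis=0)
        change = l2_norm(mu_new - mu, grid) / max(l2_norm(mu, grid), 1e-12)
        mu = mu_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Karcher mean did not converge in {max_iter} iterations", RuntimeWarning
        )

    # final alignment pass against the converged mean
    mu_curve = SrvfCurve(grid, mu)
    results = [pairwise_align(mu_curve, q, polish=polish_final) for q in qs]
    warps = [r.warp for r in results]
    aligned_srvfs = [
        SrvfCurve(grid, r.aligned_srvf.values, origin_value=q.origin_value)
        for r, q in zip(results, qs)
    ]
    amplitudes = [warp_trajectory(c, w) for c, w in zip(curves, warps)]
    phases = [w.inverse() for w in warps]

    if center_phases:
        mean_phase = WarpingFunction(grid, np.mean([p.values for p in phases], axis=0))
        mean_phase_inv = mean_phase.inverse()
        phases = [mean_phase_inv.compose(p) for p in phases]
        amplitudes = [warp_trajectory(a, mean_phase) for a in amplitudes]
        mu_srvf = warp_srvf(SrvfCurve(grid, mu), mean_phase)
        mu = mu_srvf.values
        aligned_srvfs = [
            SrvfCurve(grid, warp_srvf(q, mean_phase).values, origin_value=q.origin_value)
            for q in aligned_srvfs
        ]

    origin = float(np.mean([a.values[0] for a in amplitudes]))
    mean_srvf = SrvfCurve(grid, mu, origin_value=origin)
    mean_trajectory = from_srvf(mean_srvf, activity=curves[0].activity)
    return SeparationResult(
        mean_srvf=mean_srvf,
        mean_trajectory=mean_trajectory,
        phases=phases,
        amplitudes=amplitudes,
        aligned_srvfs=aligned_srvfs,
        iterations=iterations,
        converged=converged,
    )


def separate_phase_amplitude(
    curves: list[Trajectory],
    tol: float = 1e-4,
    max_iter: int = 20,
    center_phases: bool = True,
    polish_final: bool = True,
) -> SeparationResult:
    """Decompose each curve into amplitude and phase about the Karcher mean.

    Thin wrapper over :func:`karcher_mean`; the reconstruction invariant
    ``amplitudes[i] o phases[i] == curves[i]`` holds to interpolation accuracy.
    """
    return karcher_mean(curves, tol=tol, max_iter=max_iter,
                        center_phases=center_phases, polish_final=polish_final)


def align_to_reference(
    curves: list[Trajectory], reference: SrvfCurve
) -> list[AlignmentResult]:
    """Align each curve independently to a fixed reference mean shape.

    Used to quantify a cohort's deviation from another cohort's mean (e.g.
    patient trajectories against the healthy mean): the returned distances
    are residual shape differences that no time warp can remove.
    """
    _require_common_grid(curves)
    if reference.grid.shape != curves[0].grid.shape:
        raise GridError("reference must share the curves' grid")
    return [pairwise_align(reference, to_srvf(c)) for c in curves]
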