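"""Vertical (shape) PCA on aligned SRVFs.

After phase removal, the aligned SRVFs are mean-centered, their covariance
function is decomposed by SVD, and each curve is represented by its
projections onto the leading directions — the Vertical Principal Components
(VPCs).  On wrist-gyroscope activity data VPC1 typically encodes movement
speed (overall amplitude) and VPC2 motion asymmetry (peak height relative to
trough depth), which is what the mode-traversal and asymmetry utilities here
make inspectable and testable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import GridError, SrvfCurve, Trajectory
from .srvf import from_srvf

__all__ = [
    "ShapePcaModel",
    "fit_shape_pca",
    "project",
    "mode_traversal",
    "asymmetry_statistic",
    "integrated_mirror_asymmetry",
]


@dataclass
class ShapePcaModel:
    """Shape-PCA model: mean SRVF, orthonormal directions, spectrum.

    ``components[k]`` is orthonormal under the discrete L2 inner product
    dt * sum(u*v); ``eigenvalues`` are the covariance-operator eigenvalues
    (per-mode score variances), nonincreasing.
    """

    mean_srvf: SrvfCurve
    components: np.ndarray          # (n_retained, M), L2-orthonormal rows
    eigenvalues: np.ndarray         # (n_retained,), nonincreasing
    variance_fractions: np.ndarray  # (n_retained,), of total variance
    n_retained: int
    total_variance: float = 0.0
    activity: str = "other"

    @property
    def dt(self) -> float:
        return self.mean_srvf.dt

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid = self.mean_srvf.grid
        df = pd.DataFrame({"t": grid, "mean_srvf": self.mean_srvf.values})
        for k in range(self.n_retained):
            df[f"U{k + 1}"] = self.components[k]
        df.to_csv(out / "model.csv", index=False)
        (out / "spectrum.csv").write_text(
            pd.DataFrame(
                {
                    "component": np.arange(1, self.n_retained + 1),
                    "eigenvalue": self.eigenvalues,
                    "variance_fraction": self.variance_fractions,
                }
            ).to_csv(index=False)
        )
        (out / "metadata.json").write_text(
            json.dumps(
                {
                    "n_retained": self.n_retained,
                    "total_variance": self.total_variance,
                    "activity": self.activity,
                    "origin_value": self.mean_srvf.origin_value,
                }
            )
        )


def fit_shape_pca(
    aligned: list[SrvfCurve], n_retained: int = 3, activity: str | None = None
) -> ShapePcaModel:
    """Fit shape PCA to aligned SRVFs.

    The covariance of the mean-centered SRVFs (1/(n-1) normalization) is
    decomposed by SVD; directions are scaled so discrete L2 inner products
    approximate integrals.  Component signs are fixed so each direction has
    nonnegative inner product with the grid-wise direction of maximal raw
    variance (deterministic fits; cross-run sign alignment is handled by the
    index pipeline).
    """
    if len(aligned) < 3:
        raise ValueError("fit_shape_pca needs at least 3 aligned SRVFs")
    grid = aligned[0].grid
    for q in aligned[1:]:
        if q.grid.shape != grid.shape:
            raise GridError("aligned SRVFs must share a grid")
    n = len(aligned)
    if n_retained > n - 1:
        warnings.warn(
            f"n_retained={n_retained} exceeds n-1={n - 1}; truncating", RuntimeWarning
        )
        n_retained = n - 1
    dt = aligned[0].dt
    Q = np.stack([q.values for q in aligned])
    mean = Q.mean(axis=0)
    X = Q - mean

    # SVD of X/sqrt(n-1) diagonalizes the sample covariance; with the dt
    # weighting the covariance-operator eigenvalues are s^2 * dt.
    _, s, Vt = np.linalg.svd(X / np.sqrt(n - 1), full_matrices=False)
    eigenvalues = s**2 * dt
    total = float(eigenvalues.sum())
    k = n_retained
    components = Vt[:k] / np.sqrt(dt)  # L2-orthonormal

    # deterministic sign convention
    d = X.std(axis=0)
    for j in range(k):
        ip = dt * float(np.dot(components[j], d))
        if abs(ip) < 1e-12:
            lead = components[j][np.argmax(np.abs(components[j]))]
            ip = lead
        if ip < 0:
            components[j] = -components[j]

    origin = float(np.mean([q.origin_value for q in aligned]))
    model = ShapePcaModel(
        mean_srvf=SrvfCurve(grid, mean, origin_value=origin),
        components=components,
        eigenvalues=eigenvalues[:k],
        variance_fractions=eigenvalues[:k] / total if total > 0 else eigenvalues[:k],
        n_retained=k,
        total_variance=total,
        activity=activity or "other",
    )
    return model


def project(q: SrvfCurve, model: ShapePcaModel) -> np.ndarray:
    """VPC scores: discrete L2 inner products of the centered SRVF with each
    retained direction.  The mean shape scores zero on every component."""
    if q.grid.shape != model.mean_srvf.grid.shape:
        raise GridError("SRVF grid does not match the model grid")
    centered = q.values - model.mean_srvf.values
    return model.dt * model.components @ centered


def reconstruct(scores: np.ndarray, model: ShapePcaModel) -> SrvfCurve:
    """Inverse of :func:`project` on the retained subspace."""
    vals = model.mean_srvf.values + scores @ model.components
    return SrvfCurve(model.mean_srvf.grid, vals, origin_value=model.mean_srvf.origin_value)


def mode_traversal(
    model: ShapePcaModel, k: int, sigmas: list[float] = (-1.0, 0.0, 1.0)
) -> list[Trajectory]:
    """Curves obtained by moving s standard deviations along component k.

    Returns ``from_srvf(mu + s * sqrt(lambda_k) * U_k)`` for each requested s
    (k is 1-based).  Traversing VPC1 on activity data sweeps movement speed;
    traversing VPC2 sweeps peak/trough asymmetry.
    """
    if not 1 <= k <= model.n_retained:
        raise IndexError(f"component k={k} outside 1..{model.n_retained}")
    sd = np.sqrt(model.eigenvalues[k - 1])
    out = []
    for s in sigmas:
        vals = model.mean_srvf.values + s * sd * model.components[k - 1]
        out.append(
            from_srvf(
                SrvfCurve(model.mean_srvf.grid, vals, origin_value=model.mean_srvf.origin_value),
                activity=model.activity,
            )
        )
    return out


def asymmetry_statistic(curve: Trajectory) -> float:
    """Peak/trough imbalance: (|peak| - |trough|) / (|peak| + |trough|).

    Positive when the upward excursion dominates, negative when the downward
    one does, zero for odd-symmetric curves.  A flat curve returns 0 with a
    warning.
    """
    peak = float(np.max(curve.values))
    trough = float(np.min(curve.values))
    p, t = abs(max(peak, 0.0)), abs(min(trough, 0.0))
    if p + t < 1e-12:
        warnings.warn("flat curve: asymmetry statistic undefined, returning 0", RuntimeWarning)
        return 0.0
    return (p - t) / (p + t)


def integrated_mirror_asymmetry(curve: Trajectory) -> float:
    """Integral of |beta(t) - beta(T - t)|: 0 for curves mirror-symmetric
    about the interval midpoint."""
    mirrored = curve.values[::-1]
    return float(np.trapezoid(np.abs(curve.values - mirrored), curve.grid))
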