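"""Functional PCA of normalized breaths on the dense regular grid.

With every curve observed on the same 600-point grid, the covariance
operator discretizes exactly to a matrix problem: FPCA is PCA of the
centred data matrix with a constant quadrature weight dt. Eigenfunctions
are unit-norm in L2(dt) (units 1/sqrt(s)), eigenvalues are the score
variances, and scores are inner products of centred curves against the
eigenfunctions with dt weighting. No smoothing is applied — the median
aggregation upstream already denoises the curves — though a pre-smoothing
hook is accepted by :func:`fit_fpca`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import DT

__all__ = ["FPCAModel", "fit_fpca", "n_components_for_threshold"]


@dataclass
class FPCAModel:
    """Mean curve, orthonormal eigenfunctions, eigenvalues and scores.

    mu : (p,) mean curve in SD units.
    phi : (K, p) eigenfunctions, orthonormal under sum(phi_j*phi_k)*dt.
    lam : (K,) descending eigenvalues (score variances).
    scores : (n, K) training-curve scores xi_ik.
    """

    mu: np.ndarray
    phi: np.ndarray
    lam: np.ndarray
    scores: np.ndarray
    grid_dt: float = DT

    @property
    def n_components(self) -> int:
        return len(self.lam)

    @property
    def var_frac(self) -> np.ndarray:
        total = self.lam.sum()
        if total <= 0:
            return np.zeros_like(self.lam)
        return self.lam / total

    def project(self, curve: np.ndarray) -> np.ndarray:
        """Score vector of a curve on the model grid (dt-weighted inner
        products against the eigenfunctions); projecting mu gives zeros."""
        curve = np.asarray(curve, dtype=float)
        if curve.shape[-1] != self.mu.shape[0]:
            raise ValueError(
                f"curve has {curve.shape[-1]} samples, model grid has {self.mu.shape[0]}"
            )
        return (curve - self.mu) @ self.phi.T * self.grid_dt

    def reconstruct(self, scores: np.ndarray, k: int | None = None) -> np.ndarray:
        """mu + sum_{j<=k} xi_j*phi_j."""
        scores = np.asarray(scores, dtype=float)
        k = self.n_components if k is None else k
        if k > self.n_components:
            raise ValueError(f"k={k} exceeds the {self.n_components} fitted components")
        return self.mu + scores[..., :k] @ self.phi[:k]

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": "pao2osc-fpca-1",
            "grid_dt": self.grid_dt,
            "mu": self.mu.tolist(),
            "phi": self.phi.tolist(),
            "lam": self.lam.tolist(),
            "scores": self.scores.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FPCAModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "pao2osc-fpca-1":
            raise ValueError(f"unsupported FPCA artifact schema: {payload.get('schema')!r}")
        return cls(
            mu=np.array(payload["mu"]),
            phi=np.array(payload["phi"]),
            lam=np.array(payload["lam"]),
            scores=np.array(payload["scores"]),
            grid_dt=payload["grid_dt"],
        )


def fit_fpca(
    curves: np.ndarray,
    grid_dt: float = DT,
    presmooth: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FPCAModel:
    """Fit FPCA to an n x p matrix of curves on a common regular grid.

    Implementation: SVD of the centred matrix scaled by sqrt(dt); the
    covariance uses 1/(n-1). Components with numerically zero variance
    (relative to the leading eigenvalue) are dropped. Eigenfunction signs
    are fixed so each one's largest-magnitude element is positive.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2 curves")
    if presmooth is not None:
        curves = np.apply_along_axis(presmooth, 1, curves)
    n, p = curves.shape

    mu = curves.mean(axis=0)
    xc = curves - mu
    u, s, vt = np.linalg.svd(xc * np.sqrt(grid_dt), full_matrices=False)
    lam = s**2 / (n - 1)

    keep = lam > max(lam[0] * 1e-12, 1e-300) if lam.size and lam[0] > 0 else np.zeros(len(lam), bool)
    if not keep.any():
        # all curves identical: keep a single zero-variance component
        phi = vt[:1] / np.sqrt(grid_dt)
        return FPCAModel(mu=mu, phi=phi, lam=np.zeros(1), scores=np.zeros((n, 1)), grid_dt=grid_dt)
    u, s, vt, lam = u[:, keep], s[keep], vt[keep], lam[keep]

    phi = vt / np.sqrt(grid_dt)  # unit L2(dt) norm
    scores = u * s  # == xc @ phi.T * dt; per-component variance is lam

    # deterministic sign: largest-|.| element of each eigenfunction positive
    flip = np.sign(phi[np.arange(phi.shape[0]), np.abs(phi).argmax(axis=1)])
    flip[flip == 0] = 1.0
    phi *= flip[:, None]
    scores *= flip[None, :]

    return FPCAModel(mu=mu, phi=phi, lam=lam, scores=scores, grid_dt=grid_dt)


def n_components_for_threshold(model: FPCAModel, threshold: float = 0.95) -> int:
    """Smallest K whose cumulative variance fraction reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    vf = model.var_frac
    if vf.sum() <= 0:
        return 0
    cum = np.cumsum(vf)
    if threshold == 1.0:
        return int(np.count_nonzero(model.lam > 0))
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)
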