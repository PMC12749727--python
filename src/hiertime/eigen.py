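"""Eigenmode localization analysis.

Each eigenmode of the linearized network carries a timescale
``-1/Re(lambda)`` and a spatial loading pattern over areas.  Two metrics
quantify how localized a mode is:

- IPR(v) = sum_j |v_j|^4 for a unit vector v: 1 for a mode confined to a
  single area, 1/N for a fully distributed one;
- theta(v) = sum_{i,j} |v_i|^4 |v_j|^4 exp(-d_ij / d_bar): additionally
  weights concentration by physical proximity, with d_bar the mean
  off-diagonal inter-areal distance.

Loadings are taken from the moduli of the E-population eigenvector
entries (per-area displays and all downstream analyses use E rates);
complex-conjugate mode pairs share identical moduli and are collapsed to
one mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hiertime.connectome import Connectome
from hiertime.gradient import GradientVector, scale_gradient
from hiertime.model import ModelParams, steady_state, jacobian

__all__ = ["EigenReport", "ipr", "theta_index", "decompose", "localization_sweep"]


@dataclass
class EigenReport:
    """Per-mode eigen-analysis of a linearized network.

    ``mode_matrix`` is area x mode with nonnegative loadings, each column
    unit Euclidean norm, modes ordered by descending timescale (unstable
    modes, if any, first with timescale NaN).
    """

    eigenvalues: np.ndarray  # complex, 1/ms, one per retained mode
    mode_timescales: np.ndarray  # ms; NaN for Re(lambda) >= 0
    mode_matrix: np.ndarray  # (n_areas, n_modes)
    ipr: np.ndarray
    theta: np.ndarray
    d_bar: float
    stable: bool

    @property
    def mean_ipr(self) -> float:
        return float(np.mean(self.ipr))

    @property
    def mean_theta(self) -> float:
        return float(np.mean(self.theta))

    @property
    def timescale_sd(self) -> float:
        ts = self.mode_timescales[np.isfinite(self.mode_timescales)]
        return float(np.std(ts))

    @property
    def max_timescale(self) -> float:
        ts = self.mode_timescales[np.isfinite(self.mode_timescales)]
        return float(np.max(ts)) if ts.size else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue_re": self.eigenvalues.real,
                "eigenvalue_im": self.eigenvalues.imag,
                "timescale_ms": self.mode_timescales,
                "ipr": self.ipr,
                "theta": self.theta,
            }
        )


def ipr(v: np.ndarray) -> float:
    """Inverse participation ratio of a unit vector: sum |v_j|^4."""
    v = np.asarray(v)
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"vector norm {norm} is not 1")
    return float(np.sum(np.abs(v) ** 4))


def theta_index(v: np.ndarray, dist: np.ndarray) -> float:
    """Distance-weighted localization: sum_ij |v_i|^4 |v_j|^4 e^(-d_ij/d_bar).

    d_bar averages off-diagonal distances only (diagonal zeros would bias
    the mean down).
    """
    v = np.asarray(v)
    dist = np.asarray(dist, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("theta requires at least 2 areas")
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"vector norm {norm} is not 1")
    off = ~np.eye(n, dtype=bool)
    d_bar = dist[off].mean()
    a4 = np.abs(v) ** 4
    return float(a4 @ np.exp(-dist / d_bar) @ a4)


def decompose(
    J: np.ndarray,
    n_areas: int,
    dist: np.ndarray,
    include_inhibitory: bool = False,
) -> EigenReport:
    """Eigen-decompose a 2N x 2N Jacobian into per-mode localization metrics.

    Loadings default to the moduli of the E-population entries of each
    eigenvector (``include_inhibitory=True`` combines E and I per area by
    root-sum-of-squares), renormalized to unit norm.  Conjugate pairs are
    collapsed by keeping the member with nonnegative imaginary part.
    Modes with numerically zero E-loading are excluded from the metrics.
    """
    J = np.asarray(J, dtype=float)
    evals, evecs = np.linalg.eig(J)
    # real matrices yield exact conjugate pairs; keep the Im >= 0 member
    keep = evals.imag >= 0
    evals = evals[keep]
    evecs = evecs[:, keep]

    if include_inhibitory:
        load = np.sqrt(
            np.abs(evecs[:n_areas]) ** 2 + np.abs(evecs[n_areas:]) ** 2
        )
    else:
        load = np.abs(evecs[:n_areas])
    norms = np.linalg.norm(load, axis=0)
    nz = norms > 1e-12
    evals = evals[nz]
    load = load[:, nz] / norms[nz]

    timescales = np.where(evals.real < 0, -1.0 / evals.real, np.nan)
    order = np.argsort(-np.nan_to_num(timescales, nan=np.inf))
    evals = evals[order]
    load = load[:, order]
    timescales = timescales[order]

    n = n_areas
    off = ~np.eye(n, dtype=bool)
    d_bar = float(np.asarray(dist, dtype=float)[off].mean())
    kern = np.exp(-np.asarray(dist, dtype=float) / d_bar)
    a4 = load**4
    ipr_vals = a4.sum(axis=0)
    theta_vals = np.einsum("im,ij,jm->m", a4, kern, a4)

    return EigenReport(
        eigenvalues=evals,
        mode_timescales=timescales,
        mode_matrix=load,
        ipr=ipr_vals,
        theta=theta_vals,
        d_bar=d_bar,
        stable=bool(np.all(evals.real < 0)),
    )


def localization_sweep(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector,
    gamma_grid: np.ndarray,
    mode: str = "plain",
    baseline_E: float = 10.0,
    baseline_I: float = 0.0,
) -> pd.DataFrame:
    """Localization metrics as the gradient slope gamma is varied.

    For each gamma the gradient is rescaled, the operating point and
    Jacobian recomputed, and (gamma, mean_ipr, mean_theta, timescale_sd,
    max_timescale, stable) emitted.  Instability at some gamma flags the
    row and the sweep continues.
    """
    rows = []
    for gamma in np.asarray(gamma_grid, dtype=float):
        hg = scale_gradient(h, gamma, mode=mode)
        try:
            fp = steady_state(params, conn, hg, baseline_E, baseline_I)
            J = jacobian(params, conn, hg, active_E=fp[2], active_I=fp[3])
            rep = decompose(J, conn.n_areas, conn.dist)
            rows.append(
                {
                    "gamma": gamma,
                    "mean_ipr": rep.mean_ipr,
                    "mean_theta": rep.mean_theta,
                    "timescale_sd": rep.timescale_sd,
                    "max_timescale": rep.max_timescale,
                    "stable": rep.stable,
                }
            )
        except RuntimeError:
            rows.append(
                {
                    "gamma": gamma,
                    "mean_ipr": np.nan,
                    "mean_theta": np.nan,
                    "timescale_sd": np.nan,
                    "max_timescale": np.nan,
                    "stable": False,
                }
            )
    return pd.DataFrame(rows)
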