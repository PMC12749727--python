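"""Structure-function connectivity comparison.

Functional connectivity (FC) is the Pearson correlation matrix of E-rate
activity across areas; structural connectivity (SC) is the FLN matrix.
Their (dis)agreement is quantified as ``1 - |rho|`` with rho the Pearson
correlation between corresponding FC and SC entries — globally over all
area pairs, per target area over its incoming connections, or grouped by
subnetwork labels.

FC can be computed two ways: empirically from a simulated noise-driven
trajectory, or analytically from the stable linearization.  For the linear
system dx = J x dt + B dW the stationary covariance solves the Lyapunov
equation J S + S J' + B B' = 0; FC is the correlation form of its E-block.
The analytic route is exact up to rectification effects and serves as the
fast path for parameter sweeps, with the simulation as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from hiertime.connectome import Connectome
from hiertime.gradient import GradientVector
from hiertime.model import ModelParams, RateTrajectory, steady_state, jacobian, spectral_abscissa

__all__ = ["FCSCReport", "analytic_fc", "empirical_fc", "fc_sc_dissimilarity"]


@dataclass
class FCSCReport:
    fc: np.ndarray
    sc: np.ndarray  # matrix actually used for the comparison
    rho_global: float | None
    dissimilarity_global: float | None
    per_area: np.ndarray | None = None  # 1 - |rho_i| over incoming connections
    subnet_summary: pd.DataFrame | None = None
    settings: dict | None = None


def analytic_fc(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    noise_sd_E: float = 0.5,
    noise_sd_I: float = 0.5,
    baseline_E: float = 10.0,
    baseline_I: float = 0.0,
) -> np.ndarray:
    """Stationary E-rate correlation matrix of the linearized network.

    Noise enters the rate equations as white current noise of standard
    deviation ``noise_sd`` pA (per sqrt(ms)) in each population's input,
    matching the scaling used by ``simulate``; the induced rate diffusion
    is ``beta_X * noise_sd_X / tau_X`` for active populations.
    """
    n = conn.n_areas
    fp = steady_state(params, conn, h, baseline_E, baseline_I)
    J = jacobian(params, conn, h, active_E=fp[2], active_I=fp[3])
    if spectral_abscissa(J) >= 0:
        raise RuntimeError("unstable linearization: analytic FC undefined")
    bE = np.where(fp[2], params.beta_E * noise_sd_E / params.tau_E, 0.0)
    bI = np.where(fp[3], params.beta_I * noise_sd_I / params.tau_I, 0.0)
    Q = np.diag(np.concatenate([bE, bI]) ** 2)
    sigma = linalg.solve_continuous_lyapunov(J, -Q)
    sE = sigma[:n, :n]
    d = np.sqrt(np.diag(sE))
    if np.any(d <= 0):
        raise RuntimeError("singular stationary covariance")
    fc = sE / np.outer(d, d)
    np.fill_diagonal(fc, 1.0)
    return 0.5 * (fc + fc.T)


def empirical_fc(traj: RateTrajectory, discard_ms: float = 0.0) -> np.ndarray:
    """Pearson correlation of E rates after discarding the initial transient."""
    keep = traj.times >= discard_ms
    if keep.sum() < 3:
        raise ValueError("discard_ms leaves too few samples")
    x = traj.rE[:, keep]
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant E-rate channel(s) at area indices {dead.tolist()}")
    fc = np.corrcoef(x)
    np.fill_diagonal(fc, 1.0)
    return fc


def _pair_dissimilarity(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho = stats.pearsonr(x, y).statistic
    return float(rho), float(1.0 - abs(rho))


def fc_sc_dissimilarity(
    fc: np.ndarray,
    conn: Connectome,
    scope: str = "global",
    sc_transform: str = "raw",
) -> FCSCReport:
    """FC-SC dissimilarity 1 - |rho| at the requested scope.

    global: rho over all off-diagonal pairs, SC symmetrized as
    (FLN + FLN')/2.  per_area: for each target i, rho between FC row i and
    the incoming FLN row i over j != i.  by_subnet: per-area values grouped
    by the connectome's subnetwork labels.  ``sc_transform='log'`` compares
    against log10 FLN, excluding zero-FLN entries.
    """
    fc = np.asarray(fc, dtype=float)
    n = conn.n_areas
    if fc.shape != (n, n):
        raise ValueError(f"fc shape {fc.shape} does not match {n} areas")
    if scope not in ("global", "per_area", "by_subnet"):
        raise ValueError(f"unknown scope {scope!r}")
    if sc_transform not in ("raw", "log"):
        raise ValueError(f"unknown sc_transform {sc_transform!r}")

    sym = 0.5 * (conn.fln + conn.fln.T)
    off = ~np.eye(n, dtype=bool)
    mask = off & ((sym > 0) if sc_transform == "log" else np.ones_like(off))
    sc_used = np.log10(np.where(sym > 0, sym, np.nan)) if sc_transform == "log" else sym
    x = fc[mask]
    y = (np.log10(sym[mask]) if sc_transform == "log" else sym[mask])
    if x.size < 3:
        raise ValueError("fewer than 3 valid entry pairs for global rho")
    rho_g, dis_g = _pair_dissimilarity(x, y)

    per_area = None
    subnet_summary = None
    if scope in ("per_area", "by_subnet"):
        if n < 4:
            raise ValueError("per-area dissimilarity needs at least 4 areas")
        per_area = np.empty(n)
        for i in range(n):
            j = np.flatnonzero((np.arange(n) != i))
            row_sc = conn.fln[i, j]
            row_fc = fc[i, j]
            if sc_transform == "log":
                keep = row_sc > 0
                row_fc, row_sc = row_fc[keep], np.log10(row_sc[keep])
            if row_sc.size < 3 or np.std(row_sc) == 0 or np.std(row_fc) == 0:
                per_area[i] = np.nan
                continue
            _, per_area[i] = _pair_dissimilarity(row_fc, row_sc)
    if scope == "by_subnet":
        if conn.subnet is None:
            raise ValueError("connectome has no subnetwork labels")
        df = pd.DataFrame({"subnet": conn.subnet, "dissimilarity": per_area})
        subnet_summary = (
            df.groupby("subnet")["dissimilarity"].agg(["mean", "std", "count"]).reset_index()
        )

    return FCSCReport(
        fc=fc,
        sc=sym if sc_transform == "raw" else sc_used,
        rho_global=rho_g,
        dissimilarity_global=dis_g,
        per_area=per_area,
        subnet_summary=subnet_summary,
        settings={"scope": scope, "sc_transform": sc_transform,
                  "sc_symmetrized_global": True, "per_area_directed": True},
    )
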