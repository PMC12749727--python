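"""Pulse-stimulus propagation experiments.

A square current pulse (default 200 ms) is applied to the excitatory
population of a target area, starting from the noise-free fixed point, and
every area's peak response — the maximum deviation of its E rate from the
pre-stimulus baseline — is recorded with its latency.  Condition
comparisons (feedback deletion, gradient removal, ...) are expressed as
per-area peak ratios, and the coupling sweep probes propagation and
integration as the long-range E->E strength approaches its critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hiertime.connectome import Connectome
from hiertime.gradient import GradientVector
from hiertime.model import (
    ModelParams,
    InputProtocol,
    steady_state,
    jacobian,
    spectral_abscissa,
    simulate,
    critical_coupling,
)
from hiertime.eigen import decompose

__all__ = ["PeakResponseTable", "pulse_response", "compare_conditions", "coupling_sweep"]


@dataclass
class PeakResponseTable:
    """Per-area peak responses to a pulse stimulus.

    ``table`` columns: area, peak_hz (max E-rate deviation from baseline),
    latency_ms (time of peak after pulse onset).
    """

    table: pd.DataFrame
    condition: str
    stimulus: dict

    @property
    def peaks(self) -> np.ndarray:
        return self.table["peak_hz"].to_numpy()


def pulse_response(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    target_area: int | str,
    amplitude: float = 20.0,
    duration: float = 200.0,
    record_ms: float = 2200.0,
    dt: float = 0.25,
    baseline_E: float = 10.0,
    baseline_I: float = 0.0,
    condition: str = "control",
) -> PeakResponseTable:
    """Simulate a pulse to one area's E population from the fixed point.

    Peaks are deviations from the pre-pulse fixed point (not absolute
    rates), so conditions with different baselines remain comparable.
    Raises when the baseline operating point is unstable.
    """
    if isinstance(target_area, str):
        target_idx = conn.areas.index(target_area)
    else:
        target_idx = int(target_area)
    fp = steady_state(params, conn, h, baseline_E, baseline_I)
    J = jacobian(params, conn, h, active_E=fp[2], active_I=fp[3])
    if spectral_abscissa(J) >= 0:
        raise RuntimeError("unstable baseline: pulse response undefined")

    protocol = InputProtocol(
        baseline_E=baseline_E,
        baseline_I=baseline_I,
        pulse_targets=[target_idx],
        pulse_onset=0.0,
        pulse_duration=duration,
        pulse_amplitude=amplitude,
        pulse_population="E",
    )
    traj = simulate(
        params, conn, h, protocol, duration=record_ms, dt=dt,
        r0_E=fp[0], r0_I=fp[1],
    )
    dev = traj.rE - fp[0][:, None]
    peak_idx = np.argmax(dev, axis=1)
    peaks = dev[np.arange(conn.n_areas), peak_idx]
    latency = traj.times[peak_idx]
    table = pd.DataFrame(
        {"area": conn.areas, "peak_hz": np.maximum(peaks, 0.0), "latency_ms": latency}
    )
    return PeakResponseTable(
        table=table,
        condition=condition,
        stimulus={
            "target_area": conn.areas[target_idx],
            "amplitude_pa": amplitude,
            "duration_ms": duration,
            "record_ms": record_ms,
            "dt_ms": dt,
        },
    )


def compare_conditions(
    baseline: PeakResponseTable, variants: list[PeakResponseTable]
) -> pd.DataFrame:
    """Per-area peak differences and ratios of each variant vs the baseline.

    Ratios are NaN where the baseline peak is zero; the summary row metric
    is the mean log-ratio over areas with positive peaks in both tables.
    """
    base = baseline.table.set_index("area")["peak_hz"]
    rows = []
    for var in variants:
        if list(var.table["area"]) != list(baseline.table["area"]):
            raise ValueError(
                f"area sets differ between baseline and condition {var.condition!r}"
            )
        v = var.table.set_index("area")["peak_hz"]
        ratio = np.where(base > 0, v / base.replace(0, np.nan), np.nan)
        ok = (base > 0) & (v > 0)
        mean_log_ratio = float(np.mean(np.log(v[ok] / base[ok]))) if ok.any() else np.nan
        for area in base.index:
            rows.append(
                {
                    "condition": var.condition,
                    "area": area,
                    "peak_base_hz": base[area],
                    "peak_var_hz": v[area],
                    "difference_hz": v[area] - base[area],
                    "ratio": v[area] / base[area] if base[area] > 0 else np.nan,
                    "mean_log_ratio": mean_log_ratio,
                }
            )
    return pd.DataFrame(rows)


def coupling_sweep(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    mu_IE_values: list[float],
    lambda_fractions: list[float],
    target_area: int | str,
    readout_area: int | str,
    amplitude: float = 20.0,
    duration: float = 200.0,
    record_ms: float = 2200.0,
    dt: float = 0.25,
    baseline_E: float = 10.0,
    baseline_I: float = 0.0,
) -> pd.DataFrame:
    """Propagation/integration trade-off against the critical coupling.

    For each mu_IE the critical long-range E->E strength mu*_EE is found by
    bisection; mu_EE is then set to each lambda * mu*_EE (lambda <= 1), the
    pulse peak at the readout area and the mean IPR recorded.  lambda = 1
    rows are marginal and flagged; failures flag the row and the sweep
    continues.
    """
    if any(lam > 1 for lam in lambda_fractions):
        raise ValueError("lambda fractions must be <= 1")
    if isinstance(readout_area, str):
        readout_idx = conn.areas.index(readout_area)
    else:
        readout_idx = int(readout_area)
    rows = []
    for mu_IE in mu_IE_values:
        p_ie = params.with_(mu_IE=mu_IE)
        mu_star = critical_coupling(
            p_ie, conn, h, knob="mu_EE",
            baseline_E=baseline_E, baseline_I=baseline_I,
        )
        for lam in lambda_fractions:
            row = {
                "mu_IE": mu_IE,
                "lambda": lam,
                "mu_EE_star": mu_star,
                "mu_EE": lam * mu_star,
                "marginal": lam >= 1.0,
            }
            try:
                p = p_ie.with_(mu_EE=lam * mu_star)
                fp = steady_state(p, conn, h, baseline_E, baseline_I)
                J = jacobian(p, conn, h, active_E=fp[2], active_I=fp[3])
                rep = decompose(J, conn.n_areas, conn.dist)
                resp = pulse_response(
                    p, conn, h, target_area, amplitude=amplitude,
                    duration=duration, record_ms=record_ms, dt=dt,
                    baseline_E=baseline_E, baseline_I=baseline_I,
                )
                row.update(
                    peak_hz=float(resp.table["peak_hz"].iloc[readout_idx]),
                    mean_ipr=rep.mean_ipr,
                    mean_theta=rep.mean_theta,
                    ok=True,
                )
            except (RuntimeError, ValueError) as e:
                row.update(peak_hz=np.nan, mean_ipr=np.nan, mean_theta=np.nan,
                           ok=False, error=str(e))
            rows.append(row)
    return pd.DataFrame(rows)
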