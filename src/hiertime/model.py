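"""Threshold-linear E/I rate model over a weighted directed connectome.

Each cortical area *i* holds one excitatory and one inhibitory population
with firing rates ``rE_i``, ``rI_i`` (Hz) evolving as

    tau_E drE_i/dt = -rE_i + beta_E [ (1+eta_E h_i) w_EE rE_i - w_EI rI_i
                      + (1+eta_E h_i) mu_EE sum_j FLN_ij rE_j + I_ext_E_i ]_+
    tau_I drI_i/dt = -rI_i + beta_I [ (1+eta_I h_i) w_IE rE_i - w_II rI_i
                      + (1+eta_I h_i) mu_IE sum_j FLN_ij rE_j + I_ext_I_i ]_+

with [.]_+ the rectifier.  ``h_i`` is the composite gradient of excitation:
a per-area scalar in [0, 1) scaling all excitatory inputs of the target
area, a proxy for dendritic spine count.  Units throughout: time in ms,
rates in Hz, currents in pA; beta in Hz/pA and weights in pA/Hz so that
beta*w is dimensionless.

The optional delayed variant applies every inter-areal term with lag
``d_ij / v_ax`` and every local term with a fixed local delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hiertime.connectome import Connectome
from hiertime.gradient import GradientVector

__all__ = [
    "ModelParams",
    "InputProtocol",
    "RateTrajectory",
    "steady_state",
    "jacobian",
    "simulate",
    "spectral_abscissa",
    "critical_coupling",
]


@dataclass
class ModelParams:
    """Rate-model constants (defaults are the calibrated marmoset set)."""

    tau_E: float = 20.0  # ms
    tau_I: float = 10.0  # ms
    beta_E: float = 0.066  # Hz/pA
    beta_I: float = 0.351  # Hz/pA
    eta_E: float = 0.685
    eta_I: float = 0.76
    w_EE: float = 24.4  # pA/Hz
    w_EI: float = 19.7  # pA/Hz
    w_IE: float = 11.66  # pA/Hz
    w_II: float = 12.5  # pA/Hz
    mu_EE: float = 67.4  # pA/Hz
    mu_IE: float = 49.81  # pA/Hz
    delays_enabled: bool = False
    v_ax: float = 3.5  # axonal conduction velocity, m/s (mm/ms)
    local_delay: float = 2.0  # ms

    def __post_init__(self) -> None:
        for name in (
            "tau_E", "tau_I", "beta_E", "beta_I", "w_EE", "w_EI",
            "w_IE", "w_II", "mu_EE", "mu_IE",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class InputProtocol:
    """External-current protocol: per-area baselines, white noise, optional pulse.

    Baselines may be scalars (broadcast) or per-area arrays (pA).  Noise is
    white: each Euler step adds ``noise_sd * N(0,1) / sqrt(dt)`` pA to the
    bracket argument.  The pulse adds ``amplitude`` pA to the chosen
    population of the target areas during [onset, onset + duration) ms.
    """

    baseline_E: float | np.ndarray = 10.0  # pA
    baseline_I: float | np.ndarray = 0.0  # pA
    noise_sd_E: float = 0.0  # pA
    noise_sd_I: float = 0.0  # pA
    pulse_targets: list[int] = field(default_factory=list)
    pulse_onset: float = 0.0  # ms
    pulse_duration: float = 200.0  # ms
    pulse_amplitude: float = 0.0  # pA
    pulse_population: str = "E"
    seed: int = 0


@dataclass
class RateTrajectory:
    """Simulated E/I rates on a uniform time grid (ms, Hz)."""

    times: np.ndarray
    rE: np.ndarray  # (n_areas, n_times)
    rI: np.ndarray
    dt: float
    params: ModelParams
    protocol: InputProtocol
    seed: int


def _gradient_array(h: GradientVector | np.ndarray | None, n: int) -> np.ndarray:
    if h is None:
        return np.zeros(n)
    arr = h.h if isinstance(h, GradientVector) else np.asarray(h, dtype=float)
    arr = np.broadcast_to(np.atleast_1d(arr), (n,)).astype(float)
    if np.any(arr >= 1):
        raise ValueError("gradient values must be < 1")
    return arr


def _drive_matrices(params: ModelParams, conn: Connectome, h: np.ndarray):
    """Effective input weights: currents to E and I brackets from (rE, rI)."""
    gE = 1.0 + params.eta_E * h  # target-area scaling of excitatory inputs to E
    gI = 1.0 + params.eta_I * h  # ... to I
    n = conn.n_areas
    # W_XE[i, j]: current into X-bracket of area i per Hz of rE_j
    W_EE = np.diag(gE * params.w_EE) + gE[:, None] * params.mu_EE * conn.fln
    W_IE = np.diag(gI * params.w_IE) + gI[:, None] * params.mu_IE * conn.fln
    w_EI = np.full(n, params.w_EI)
    w_II = np.full(n, params.w_II)
    return W_EE, W_IE, w_EI, w_II


def steady_state(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    baseline_E: float | np.ndarray = 10.0,
    baseline_I: float | np.ndarray = 0.0,
    max_iter: int = 100,
):
    """Fixed point of the rectified system by active-set iteration.

    Populations whose bracket argument is positive are 'linear' (active);
    silenced populations sit at rate 0.  Starting from the all-active set,
    the linear fixed point of the current active set is solved exactly and
    the active set updated from the resulting bracket arguments, until it
    stabilizes.

    Returns
    -------
    (rE, rI, active_E, active_I) where the active flags mark populations in
    the linear regime at the fixed point.
    """
    n = conn.n_areas
    h = _gradient_array(h, n)
    I_E = np.broadcast_to(np.atleast_1d(np.asarray(baseline_E, float)), (n,)).copy()
    I_I = np.broadcast_to(np.atleast_1d(np.asarray(baseline_I, float)), (n,)).copy()
    W_EE, W_IE, w_EI, w_II = _drive_matrices(params, conn, h)

    # stacked linear system for r = [rE; rI]:  r = B (W r + I)  on active rows
    W = np.zeros((2 * n, 2 * n))
    W[:n, :n] = W_EE
    W[:n, n:] = -np.diag(w_EI)
    W[n:, :n] = W_IE
    W[n:, n:] = -np.diag(w_II)
    beta = np.concatenate([np.full(n, params.beta_E), np.full(n, params.beta_I)])
    I = np.concatenate([I_E, I_I])

    active = np.ones(2 * n, dtype=bool)
    seen: set[bytes] = set()
    for _ in range(max_iter):
        r = np.zeros(2 * n)
        idx = np.flatnonzero(active)
        if idx.size:
            A = np.eye(idx.size) - (beta[idx, None] * W[np.ix_(idx, idx)])
            try:
                r_act = np.linalg.solve(A, beta[idx] * I[idx])
            except np.linalg.LinAlgError as e:
                raise RuntimeError(f"singular active-set system: {e}") from e
            r[idx] = r_act
        arg = W @ r + I
        new_active = arg > 0
        # a population can only be self-consistently active with positive rate
        new_active &= ~((r < 0) & active)
        if np.array_equal(new_active, active):
            if np.any(r < -1e-10):
                raise RuntimeError("no consistent active set (negative rates)")
            r = np.maximum(r, 0.0)
            resid = np.max(np.abs(r - beta * np.maximum(arg, 0.0)))
            if resid > 1e-10:
                raise RuntimeError(f"fixed-point residual {resid:.2e} exceeds 1e-10 Hz")
            return r[:n], r[n:], active[:n].copy(), active[n:].copy()
        key = new_active.tobytes()
        if key in seen:
            raise RuntimeError("active-set iteration cycled: unstable regime?")
        seen.add(key)
        active = new_active
    raise RuntimeError("active-set iteration did not converge")


def jacobian(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    fixed_point=None,
    active_E: np.ndarray | None = None,
    active_I: np.ndarray | None = None,
) -> np.ndarray:
    """2N x 2N Jacobian (1/ms) of the rate equations at a fixed point.

    Rows/columns are ordered [E_1..E_N, I_1..I_N].  Silenced populations
    (rectifier argument <= 0) contribute only their leak term -1/tau.  If no
    regime flags are given, the all-linear regime is assumed.
    """
    n = conn.n_areas
    h = _gradient_array(h, n)
    if fixed_point is not None and active_E is None:
        # allow passing the full steady_state return tuple
        if len(fixed_point) == 4:
            _, _, active_E, active_I = fixed_point
    if active_E is None:
        active_E = np.ones(n, dtype=bool)
    if active_I is None:
        active_I = np.ones(n, dtype=bool)
    active_E = np.asarray(active_E, dtype=bool)
    active_I = np.asarray(active_I, dtype=bool)

    W_EE, W_IE, w_EI, w_II = _drive_matrices(params, conn, h)
    gainE = np.where(active_E, params.beta_E, 0.0)
    gainI = np.where(active_I, params.beta_I, 0.0)

    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = (gainE[:, None] * W_EE - np.eye(n)) / params.tau_E
    J[:n, n:] = np.diag(-gainE * w_EI) / params.tau_E
    J[n:, :n] = (gainI[:, None] * W_IE) / params.tau_I
    J[n:, n:] = (np.diag(-gainI * w_II) - np.eye(n)) / params.tau_I
    return J


def spectral_abscissa(J: np.ndarray) -> float:
    """Largest real part of the eigenvalues (1/ms); the stability margin."""
    J = np.asarray(J)
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite Jacobian entries")
    return float(np.max(np.linalg.eigvals(J).real))


def _abscissa_at(params, conn, h, baseline_E, baseline_I):
    """Spectral abscissa at the operating point; +inf when the fixed point
    is lost (treated as the unstable side during bracketing)."""
    try:
        fp = steady_state(params, conn, h, baseline_E, baseline_I)
    except RuntimeError:
        return np.inf
    J = jacobian(params, conn, h, active_E=fp[2], active_I=fp[3])
    return spectral_abscissa(J)


def critical_coupling(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    knob: str = "mu_EE",
    bracket: tuple[float, float] | None = None,
    baseline_E: float | np.ndarray = 10.0,
    baseline_I: float | np.ndarray = 0.0,
    rtol: float = 1e-6,
) -> float:
    """Critical value of a coupling knob: the largest value at which the
    network (fixed point re-solved at every trial) remains stable.

    ``knob``: 'mu_EE' scales the long-range E->E coupling; 'w_EE_effective'
    sets the effective local E->E weight (1+eta_E h) w_EE directly, which
    for a decoupled area has the closed-form critical value
    ``(1 + beta_E w_EI beta_I w_IE / (1 + beta_I w_II)) / beta_E``.

    Bisection on the sign of the spectral abscissa to relative tolerance
    ``rtol``; a trial value where the fixed point no longer exists counts
    as unstable.
    """
    if knob not in ("mu_EE", "w_EE_effective"):
        raise ValueError(f"unknown knob {knob!r}")
    if knob == "mu_EE" and not np.any(conn.fln):
        raise ValueError("mu_EE has no effect: FLN matrix is all zero")

    n = conn.n_areas
    h_arr = _gradient_array(h, n)

    def trial(value: float) -> float:
        if knob == "mu_EE":
            p = params.with_(mu_EE=value)
            return _abscissa_at(p, conn, h_arr, baseline_E, baseline_I)
        return _abscissa_at_weff(params, conn, h_arr, value, baseline_E, baseline_I)

    # The stable region need not extend down to zero coupling: with strong
    # long-range drive onto I, weakly E-E-coupled networks destabilize via a
    # mutual-disinhibition (competition) mode.  The critical value sought is
    # the UPPER edge of the stability window, so the default bracket starts
    # at the current (assumed stable) operating value.
    if bracket is None:
        current = params.mu_EE if knob == "mu_EE" else params.w_EE
        bracket = (max(current, 1e-6), max(1.2 * current, 1.0))
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = trial(lo), trial(hi)
    # auto-expand the upper end until instability is bracketed
    expand = 0
    while f_hi < 0 and expand < 60:
        hi *= 1.5
        f_hi = trial(hi)
        expand += 1
    if f_lo >= 0:
        # the given operating point is itself unstable; the stability window
        # may sit elsewhere (it shifts with the other couplings).  Coarse-scan
        # for the window's highest stable point and bisect from there.
        grid = np.linspace(hi / 50.0, hi, 50)
        stable = [g for g in grid if trial(g) < 0]
        if not stable:
            raise RuntimeError(
                f"no stable operating point found in (0, {hi:g}] for knob {knob!r}"
            )
        lo = max(stable)
        above = grid[grid > lo]
        hi = float(above[0]) if above.size else 1.5 * lo
        f_lo, f_hi = trial(lo), trial(hi)
    if f_lo >= 0 or f_hi < 0:
        raise RuntimeError(
            f"no sign change in bracket [{lo:g}, {hi:g}] "
            f"(abscissa {f_lo:g} .. {f_hi:g})"
        )
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if trial(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _abscissa_at_weff(params, conn, h_arr, w_eff, baseline_E, baseline_I):
    """Abscissa with the effective local E->E weight (1+eta_E h) w_EE forced
    to `w_eff` uniformly (used by the w_EE_effective knob)."""
    # Build a parameter set whose local E->E term is exactly w_eff after the
    # gradient factor is applied; only valid for uniform h (the decoupled-area
    # analyses use h=0), otherwise the first area's factor is used.
    factor = 1.0 + params.eta_E * h_arr
    if not np.allclose(factor, factor[0]):
        raise ValueError("w_EE_effective knob requires a uniform gradient")
    p = params.with_(w_EE=w_eff / factor[0])
    return _abscissa_at(p, conn, h_arr, baseline_E, baseline_I)


def simulate(
    params: ModelParams,
    conn: Connectome,
    h: GradientVector | np.ndarray | None,
    protocol: InputProtocol,
    duration: float,
    dt: float = 0.05,
    r0_E: np.ndarray | None = None,
    r0_I: np.ndarray | None = None,
) -> RateTrajectory:
    """Forward-Euler (Euler-Maruyama with noise) integration of the network.

    ``dt`` must satisfy dt <= tau_I / 20.  With ``params.delays_enabled``,
    inter-areal inputs are lagged by ``dist/v_ax`` (rounded to the nearest
    step, ties up) and local terms by ``local_delay`` (which must be a
    multiple of dt; 0 is allowed and reproduces the undelayed scheme
    exactly).  History before t=0 equals the initial state.  Identical
    seeds give bit-identical trajectories.
    """
    if dt > params.tau_I / 20 + 1e-12:
        raise ValueError(f"dt={dt} ms too large; need dt <= tau_I/20 = {params.tau_I / 20} ms")
    n = conn.n_areas
    h_arr = _gradient_array(h, n)
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    W_EE, W_IE, w_EI, w_II = _drive_matrices(params, conn, h_arr)
    gE = 1.0 + params.eta_E * h_arr
    gI = 1.0 + params.eta_I * h_arr
    local_EE = gE * params.w_EE
    local_IE = gI * params.w_IE
    long_EE = gE[:, None] * params.mu_EE * conn.fln
    long_IE = gI[:, None] * params.mu_IE * conn.fln

    I_E0 = np.broadcast_to(np.atleast_1d(np.asarray(protocol.baseline_E, float)), (n,))
    I_I0 = np.broadcast_to(np.atleast_1d(np.asarray(protocol.baseline_I, float)), (n,))

    rng = np.random.default_rng(protocol.seed)
    sqdt = np.sqrt(dt)

    rE = np.zeros((n, n_steps + 1))
    rI = np.zeros((n, n_steps + 1))
    rE[:, 0] = 0.0 if r0_E is None else np.asarray(r0_E, float)
    rI[:, 0] = 0.0 if r0_I is None else np.asarray(r0_I, float)

    pulse_on = (
        protocol.pulse_amplitude != 0.0 and len(protocol.pulse_targets) > 0
    )
    pulse_vec = np.zeros(n)
    if pulse_on:
        pulse_vec[np.asarray(protocol.pulse_targets, dtype=int)] = protocol.pulse_amplitude

    delays = params.delays_enabled
    if delays:
        if params.local_delay < 0:
            raise ValueError("local_delay must be >= 0")
        ld_steps = int(round(params.local_delay / dt))
        if abs(ld_steps * dt - params.local_delay) > 1e-9:
            raise ValueError("local_delay must be an integer multiple of dt")
        # mm / (m/s) = ms
        d_steps = np.floor(conn.dist / params.v_ax / dt + 0.5).astype(int)
        np.fill_diagonal(d_steps, 0)
        max_delay = max(int(d_steps.max()), ld_steps)
        L = max_delay + 1
        histE = np.tile(rE[:, [0]], (1, L))  # ring buffer of rE
        histI = np.tile(rI[:, [0]], (1, L))
        cols = np.arange(n)

    for step in range(n_steps):
        t = step * dt
        cE = rE[:, step]
        cI = rI[:, step]
        if delays:
            ptr = step % L
            histE[:, ptr] = cE
            histI[:, ptr] = cI
            if step >= ld_steps:
                lE = histE[:, (step - ld_steps) % L]
                lI = histI[:, (step - ld_steps) % L]
            else:
                lE, lI = rE[:, 0], rI[:, 0]
            src_steps = step - d_steps  # (n, n) source time index per pair
            src = np.where(src_steps >= 0, src_steps % L, 0)
            early = src_steps < 0
            rE_del = histE[cols[None, :], src]
            if early.any():
                rE_del = np.where(early, rE[:, 0][None, :], rE_del)
            longE = np.einsum("ij,ij->i", long_EE, rE_del)
            longI = np.einsum("ij,ij->i", long_IE, rE_del)
            argE = local_EE * lE - params.w_EI * lI + longE
            argI = local_IE * lE - params.w_II * lI + longI
        else:
            argE = local_EE * cE - params.w_EI * cI + long_EE @ cE
            argI = local_IE * cE - params.w_II * cI + long_IE @ cE

        argE = argE + I_E0
        argI = argI + I_I0
        if pulse_on and protocol.pulse_onset <= t < protocol.pulse_onset + protocol.pulse_duration:
            if protocol.pulse_population == "E":
                argE = argE + pulse_vec
            else:
                argI = argI + pulse_vec
        if protocol.noise_sd_E > 0:
            argE = argE + protocol.noise_sd_E / sqdt * rng.standard_normal(n)
        if protocol.noise_sd_I > 0:
            argI = argI + protocol.noise_sd_I / sqdt * rng.standard_normal(n)

        nE = cE + dt / params.tau_E * (-cE + params.beta_E * np.maximum(argE, 0.0))
        nI = cI + dt / params.tau_I * (-cI + params.beta_I * np.maximum(argI, 0.0))
        if not (np.all(np.isfinite(nE)) and np.all(np.isfinite(nI))):
            raise RuntimeError(f"non-finite state at t={t + dt:.3f} ms (blow-up)")
        rE[:, step + 1] = np.maximum(nE, 0.0)
        rI[:, step + 1] = np.maximum(nI, 0.0)

    return RateTrajectory(
        times=times, rE=rE, rI=rI, dt=dt, params=params,
        protocol=protocol, seed=protocol.seed,
    )
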