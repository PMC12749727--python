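"""Synthetic connectomes and surrogate activity.

The connectome generator emulates the statistical structure the analyses
assume about a real primate connectome:

- clustered geometry: areas are scattered around a handful of cluster
  centers inside a cortex-sized box, mimicking the grouping of cortical
  areas into lobes (occipital, temporal, parietal, frontal, ...);
- an exponential distance rule (EDR): projection weight decays as
  ``exp(-d/edr_length)`` with multiplicative lognormal noise, rows
  normalized per target area as tracer-derived FLN matrices are;
- a spatially organized hierarchy: hierarchy ranks follow a noisy spatial
  axis (sensory areas at one end, association areas at the other), so
  nearby areas occupy similar hierarchical levels as in real cortex;
- an SLN matrix coupled to the hierarchy through a logistic rule, so
  projections running up the hierarchy have SLN > 0.5 (feedforward) and
  projections running down have SLN < 0.5 (feedback) — an invented but
  conventional parameterization, not a measured relation;
- a monotone ground-truth excitation gradient aligned with the hierarchy.

Surrogate activity channels are exact discrete Ornstein-Uhlenbeck (OU)
processes (stationary start, unit variance) with optional narrow-band
oscillatory components, so the spectral estimators can be calibrated
against a known Lorentzian spectrum (exponent 2, knee at 1/(2*pi*tau)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from hiertime.connectome import Connectome

__all__ = [
    "SyntheticSpec",
    "synth_connectome",
    "synth_timeseries",
    "strong_edr_spec",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic connectome generator.

    Defaults are sized for a small marmoset-like cortex: a few dozen areas
    clustered into lobes inside an ~18 mm box, EDR decay length 5 mm,
    lognormal weight scatter of just under one natural-log unit, and a
    gradient peaking at 0.6 so that the full network at the printed
    coupling parameters sits in the stable, near-critical regime.
    """

    n_areas: int = 30
    box_size: float = 18.0  # mm; cluster centers drawn inside this cube
    positions: np.ndarray | None = None  # explicit (n_areas, 3) mm, overrides box
    n_clusters: int = 5  # lobe-like groups of areas
    cluster_sd: float = 1.2  # mm, within-cluster scatter
    edr_length: float = 5.0  # mm
    weight_noise_sd: float = 0.8  # sd of log-weight noise (natural log)
    hierarchy_slope: float = 1.0
    hierarchy_axis_noise: float = 0.2  # jitter of hierarchy around the spatial axis
    sln_steepness: float = 6.0  # kappa of the logistic SLN rule
    gradient_max: float = 0.6  # peak of the ground-truth excitation gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        if self.edr_length <= 0:
            raise ValueError("edr_length must be positive")
        if not 0 <= self.gradient_max < 1:
            raise ValueError("gradient_max must be in [0, 1)")


def strong_edr_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Preset with pronounced distance structure, used for connectivity
    manipulations (FLN shuffling): larger network, short EDR length, light
    weight noise and a moderate gradient, so that eigenmodes are carried by
    groups of physically proximal areas rather than by single areas."""
    kw = dict(
        n_areas=55,
        n_clusters=6,
        edr_length=2.0,
        weight_noise_sd=0.6,
        gradient_max=0.4,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


def synth_connectome(spec: SyntheticSpec) -> Connectome:
    """Generate an EDR + lognormal-noise connectome with hierarchy-driven SLN.

    The ground-truth gradient ``h_true = gradient_max * normalized
    hierarchy rank`` is attached to the returned connectome as ``h_true``;
    the (scaled) hierarchy itself is stored in ``hierarchy_exp``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_areas

    if spec.positions is not None:
        pos = np.asarray(spec.positions, dtype=float)
        if pos.shape != (n, 3):
            raise ValueError(f"positions must have shape ({n}, 3)")
    else:
        centers = rng.uniform(0.15 * spec.box_size, 0.85 * spec.box_size,
                              size=(spec.n_clusters, 3))
        assign = rng.integers(0, spec.n_clusters, size=n)
        pos = centers[assign] + spec.cluster_sd * rng.standard_normal((n, 3))
    # resample exact duplicates (zero distance breaks the EDR ranking)
    for _ in range(10):
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        dup = (d + np.eye(n)) == 0
        if not dup.any():
            break
        warnings.warn("duplicate positions resampled", stacklevel=2)
        bad = np.unique(np.argwhere(dup)[:, 0])
        pos[bad] = rng.uniform(0.0, spec.box_size, size=(len(bad), 3))
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    log_eps = rng.normal(0.0, spec.weight_noise_sd, size=(n, n))
    fln = np.exp(-dist / spec.edr_length + log_eps)
    np.fill_diagonal(fln, 0.0)
    fln /= fln.sum(axis=1, keepdims=True)

    # hierarchy ranks follow a noisy spatial axis: rank-uniform in [0, 1]
    score = pos[:, 0] / spec.box_size + spec.hierarchy_axis_noise * rng.standard_normal(n)
    ranks = stats.rankdata(score, method="ordinal") - 1
    h_norm = ranks / (n - 1)
    hierarchy = spec.hierarchy_slope * h_norm

    diff = hierarchy[:, None] - hierarchy[None, :]  # target minus source
    sln = special.expit(spec.sln_steepness * diff)
    np.fill_diagonal(sln, 0.5)

    conn = Connectome(
        areas=[f"A{i:02d}" for i in range(n)],
        fln=fln,
        sln=sln,
        dist=dist,
        hierarchy_exp=hierarchy,
        positions=pos,
        row_normalized=True,
    )
    conn.h_true = spec.gradient_max * h_norm  # ground truth for recovery tests
    return conn


def synth_timeseries(
    taus: np.ndarray,
    duration: float,
    fs: float,
    peaks: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Exact discrete OU channels with optional oscillatory peaks.

    Parameters
    ----------
    taus:
        Per-channel decay time constants in ms.
    duration:
        Length in seconds.
    fs:
        Sampling rate in Hz.
    peaks:
        Optional list of ``(freq_hz, relative_power, bandwidth_hz)`` added to
        every channel.  Each peak is a stochastic narrow-band (complex-OU)
        oscillation whose variance is ``relative_power`` times the
        unit base variance; its spectral width is set by ``bandwidth_hz``.

    Returns
    -------
    ndarray of shape (n_channels, n_samples); each base channel is
    stationary with unit variance before peaks are added.
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if np.any(taus <= 0):
        raise ValueError("taus must be positive")
    n_samples = int(round(duration * fs))
    if n_samples < 1000:
        raise ValueError("duration * fs must be at least 1000 samples")
    dt_ms = 1000.0 / fs
    rng = np.random.default_rng(seed)

    # exact OU update: x[t+1] = a x[t] + sqrt(1-a^2) xi, stationary variance 1
    a = np.exp(-dt_ms / taus)
    noise = rng.standard_normal((len(taus), n_samples))
    x = np.empty((len(taus), n_samples))
    x[:, 0] = noise[:, 0]
    s = np.sqrt(1.0 - a**2)
    for t in range(1, n_samples):
        x[:, t] = a * x[:, t - 1] + s * noise[:, t]

    if peaks:
        for freq, rel_power, bandwidth in peaks:
            if freq >= fs / 2:
                raise ValueError(f"peak frequency {freq} Hz >= Nyquist {fs / 2} Hz")
            # complex OU rotated at the peak frequency: Lorentzian line of
            # half-width 1/(2 pi tau_b) centered at freq
            tau_b = 1.0 / (np.pi * bandwidth)  # s
            ab = np.exp((2j * np.pi * freq - 1.0 / tau_b) / fs)
            sb = np.sqrt(1.0 - abs(ab) ** 2)
            zn = (
                rng.standard_normal((len(taus), n_samples))
                + 1j * rng.standard_normal((len(taus), n_samples))
            ) / np.sqrt(2.0)
            z = np.empty((len(taus), n_samples), dtype=complex)
            z[:, 0] = zn[:, 0]
            for t in range(1, n_samples):
                z[:, t] = ab * z[:, t - 1] + sb * zn[:, t]
            osc = np.sqrt(2.0) * z.real  # unit variance
            x = x + np.sqrt(rel_power) * osc
    return x
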