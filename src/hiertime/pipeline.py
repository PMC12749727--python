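"""Scenario-driven experiment pipeline.

Every simulation scenario of the study is reachable from a single config
file (YAML or JSON), without code edits: resting-state timescale tables,
pulse-stimulus experiments, gradient-slope sweeps (plain and
mean-preserving), gradient removal, E-I balance disruption (w_EI x 1.10),
FLN shuffling with distribution summaries, feedback deletion (SLN < 0.5),
coupling sweeps against the critical mu_EE, criticality scans, and FC-SC
dissimilarity reports.

Outputs are tidy CSV tables plus a JSON manifest recording the package
version, the fully resolved config (all defaults printed) and per-stage
seeds, so a run is reproducible from its own output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hiertime import __version__
from hiertime.connectome import (
    Connectome,
    load_connectome,
    write_connectome,
    shuffle_fln,
    remove_feedback,
)
from hiertime.synth import SyntheticSpec, synth_connectome
from hiertime.gradient import GradientVector, scale_gradient
from hiertime.model import (
    ModelParams,
    InputProtocol,
    steady_state,
    jacobian,
    simulate,
    critical_coupling,
    spectral_abscissa,
)
from hiertime.spectral import SpectralConfig, estimate_timescales
from hiertime.eigen import decompose, localization_sweep
from hiertime.fc_sc import analytic_fc, empirical_fc, fc_sc_dissimilarity
from hiertime.propagation import pulse_response, compare_conditions, coupling_sweep

__all__ = ["SCENARIOS", "ScenarioError", "load_config", "run_scenario"]

SCENARIOS = (
    "resting_state",
    "stimulus",
    "gradient_sweep",
    "gradient_removed",
    "ei_disruption",
    "fln_shuffle",
    "feedback_removed",
    "coupling_sweep",
    "criticality",
    "fc_sc",
)


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _validate(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ScenarioError("config must be a mapping")
    scenario = config.get("scenario")
    if scenario not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {scenario!r}; valid names: {', '.join(SCENARIOS)}"
        )
    conn_cfg = config.get("connectome", {"synthetic": {}})
    if ("files" in conn_cfg) == ("synthetic" in conn_cfg):
        raise ScenarioError("connectome config needs exactly one of 'files'/'synthetic'")
    allowed_overrides = {f.name for f in dataclasses.fields(ModelParams)} | {
        "w_EI_scale"
    }
    for key in config.get("params", {}):
        if key not in allowed_overrides:
            raise ScenarioError(f"unknown parameter override {key!r}")
    return config


def _build_connectome(config: dict, seed: int) -> Connectome:
    conn_cfg = config.get("connectome", {"synthetic": {}})
    if "files" in conn_cfg:
        files = conn_cfg["files"]
        return load_connectome(
            files["fln"],
            files["sln"],
            files["dist"],
            annotations_path=files.get("annotations"),
            normalize_rows=files.get("normalize_rows", False),
        )
    spec_kw = dict(conn_cfg.get("synthetic", {}))
    spec_kw.setdefault("seed", seed)
    return synth_connectome(SyntheticSpec(**spec_kw))


def _build_gradient(config: dict, conn: Connectome) -> GradientVector:
    grad_cfg = config.get("gradient", {"source": "synthetic_truth"})
    source = grad_cfg.get("source", "synthetic_truth")
    if source == "synthetic_truth":
        h_true = getattr(conn, "h_true", None)
        if h_true is None:
            raise ScenarioError("connectome has no synthetic ground-truth gradient")
        return GradientVector(h=h_true, provenance="manual")
    if source == "file":
        df = pd.read_csv(grad_cfg["file"]).set_index("area")
        h = df.loc[conn.areas, "h"].to_numpy(dtype=float)
        return GradientVector(h=h, provenance="manual")
    if source == "zero":
        return GradientVector(h=np.zeros(conn.n_areas), provenance="manual")
    raise ScenarioError(f"unknown gradient source {source!r}")


def _build_params(config: dict) -> ModelParams:
    overrides = dict(config.get("params", {}))
    scale = overrides.pop("w_EI_scale", None)
    p = ModelParams(**overrides)
    if scale is not None:
        p = p.with_(w_EI=p.w_EI * scale)
    return p


def _eigen_summary(params, conn, h, baseline_E, baseline_I):
    fp = steady_state(params, conn, h, baseline_E, baseline_I)
    J = jacobian(params, conn, h, active_E=fp[2], active_I=fp[3])
    return decompose(J, conn.n_areas, conn.dist)


def run_scenario(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run one scenario; returns the output directory.

    ``config`` may be a mapping or a path to a YAML/JSON file.  Outputs are
    deterministic given (config, seed).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = _validate(config)
    scenario = config["scenario"]
    seed = int(config.get("seed", 0))
    opts = dict(config.get("options", {}))
    out = Path(output_dir or config.get("output_dir", f"out_{scenario}"))
    out.mkdir(parents=True, exist_ok=True)

    t_start = time.time()
    params = _build_params(config)
    conn = _build_connectome(config, seed)
    h = _build_gradient(config, conn)
    baseline_E = float(config.get("baseline_E", 10.0))
    baseline_I = float(config.get("baseline_I", 0.0))
    noise_E = float(config.get("noise_sd_E", 0.5))
    noise_I = float(config.get("noise_sd_I", 0.5))

    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        outputs[name] = p.name

    if scenario == "resting_state":
        duration_s = float(opts.get("duration_s", 60.0))
        dt = float(opts.get("dt_ms", 0.5))
        fs_out = float(opts.get("fs_hz", 1000.0))
        fp = steady_state(params, conn, h, baseline_E, baseline_I)
        proto = InputProtocol(
            baseline_E=baseline_E, baseline_I=baseline_I,
            noise_sd_E=noise_E, noise_sd_I=noise_I, seed=seed,
        )
        traj = simulate(params, conn, h, proto,
                        duration=(duration_s + 1.0) * 1000.0, dt=dt,
                        r0_E=fp[0], r0_I=fp[1])
        stride = max(int(round(1000.0 / fs_out / dt)), 1)
        x = traj.rE[:, ::stride][:, int(fs_out):]  # drop 1 s transient
        cfg_kw = dict(opts.get("spectral", {}))
        cfg = SpectralConfig(**cfg_kw) if cfg_kw else SpectralConfig(
            window_s=4.0, fit_range_hz=(0.25, 80.0))
        table = estimate_timescales(x, fs_out, conn.areas, cfg)
        emit("tau_table", table)

    elif scenario == "stimulus":
        target = opts.get("target_area", conn.areas[int(np.argmin(h.h))])
        resp = pulse_response(
            params, conn, h, target,
            amplitude=float(opts.get("amplitude_pa", 20.0)),
            duration=float(opts.get("duration_ms", 200.0)),
            record_ms=float(opts.get("record_ms", 2200.0)),
            dt=float(opts.get("dt_ms", 0.25)),
            baseline_E=baseline_E, baseline_I=baseline_I,
        )
        emit("peak_responses", resp.table)

    elif scenario == "gradient_sweep":
        gamma_grid = np.asarray(opts.get("gamma_grid", np.linspace(0, 1, 11)), float)
        mode = opts.get("mode", "plain")
        emit("localization_sweep",
             localization_sweep(params, conn, h, gamma_grid, mode=mode,
                                baseline_E=baseline_E, baseline_I=baseline_I))

    elif scenario == "gradient_removed":
        rows = []
        for label, hh in (("control", h), ("gradient_removed", scale_gradient(h, 0.0))):
            rep = _eigen_summary(params, conn, hh, baseline_E, baseline_I)
            df = rep.to_frame()
            df.insert(0, "condition", label)
            rows.append(df)
        emit("eigenmodes", pd.concat(rows, ignore_index=True))

    elif scenario == "ei_disruption":
        scale = float(opts.get("w_EI_scale", 1.10))
        rows = []
        for label, pp in (("control", params),
                          ("ei_disrupted", params.with_(w_EI=params.w_EI * scale))):
            rep = _eigen_summary(pp, conn, h, baseline_E, baseline_I)
            rows.append({"condition": label, "mean_ipr": rep.mean_ipr,
                         "mean_theta": rep.mean_theta,
                         "timescale_sd": rep.timescale_sd,
                         "max_timescale": rep.max_timescale})
        emit("ei_disruption", pd.DataFrame(rows))

    elif scenario == "fln_shuffle":
        n_shuffles = int(opts.get("n_shuffles", 1000))
        rep0 = _eigen_summary(params, conn, h, baseline_E, baseline_I)
        rows = [{"condition": "control", "shuffle_seed": -1,
                 "mean_ipr": rep0.mean_ipr, "mean_theta": rep0.mean_theta,
                 "timescale_sd": rep0.timescale_sd}]
        rng = np.random.default_rng(seed)
        for k in range(n_shuffles):
            s = int(rng.integers(0, 2**31 - 1))
            sh = shuffle_fln(conn, seed=s)
            try:
                rep = _eigen_summary(params, sh, h, baseline_E, baseline_I)
                rows.append({"condition": "shuffled", "shuffle_seed": s,
                             "mean_ipr": rep.mean_ipr, "mean_theta": rep.mean_theta,
                             "timescale_sd": rep.timescale_sd})
            except RuntimeError:
                rows.append({"condition": "shuffled_unstable", "shuffle_seed": s,
                             "mean_ipr": np.nan, "mean_theta": np.nan,
                             "timescale_sd": np.nan})
        emit("fln_shuffle", pd.DataFrame(rows))

    elif scenario == "feedback_removed":
        target = opts.get("target_area", conn.areas[int(np.argmin(h.h))])
        kw = dict(
            amplitude=float(opts.get("amplitude_pa", 20.0)),
            duration=float(opts.get("duration_ms", 200.0)),
            record_ms=float(opts.get("record_ms", 2200.0)),
            dt=float(opts.get("dt_ms", 0.25)),
            baseline_E=baseline_E, baseline_I=baseline_I,
        )
        base = pulse_response(params, conn, h, target, condition="control", **kw)
        variants = [
            pulse_response(params, remove_feedback(conn), h, target,
                           condition="feedback_removed", **kw),
            pulse_response(params, conn, scale_gradient(h, 0.0), target,
                           condition="gradient_removed", **kw),
        ]
        emit("condition_comparison", compare_conditions(base, variants))

    elif scenario == "coupling_sweep":
        emit("coupling_sweep", coupling_sweep(
            params, conn, h,
            mu_IE_values=list(opts.get("mu_IE_values", [24.91, 37.36, 49.81])),
            lambda_fractions=list(opts.get("lambda_fractions", [0.95, 0.97, 0.975, 1.0])),
            target_area=opts.get("target_area", conn.areas[int(np.argmin(h.h))]),
            readout_area=opts.get("readout_area", conn.areas[int(np.argmax(h.h))]),
            amplitude=float(opts.get("amplitude_pa", 20.0)),
            record_ms=float(opts.get("record_ms", 2200.0)),
            dt=float(opts.get("dt_ms", 0.25)),
            baseline_E=baseline_E, baseline_I=baseline_I,
        ))

    elif scenario == "criticality":
        rows = []
        for mu_IE in opts.get("mu_IE_values", [24.91, 37.36, 49.81]):
            p_ie = params.with_(mu_IE=float(mu_IE))
            try:
                mu_star = critical_coupling(
                    p_ie, conn, h, knob="mu_EE",
                    bracket=tuple(opts["bracket"]) if "bracket" in opts else None,
                    baseline_E=baseline_E, baseline_I=baseline_I)
            except RuntimeError as e:
                rows.append({"mu_IE": mu_IE, "mu_EE_star": np.nan, "error": str(e)})
                continue
            rows.append({"mu_IE": mu_IE, "mu_EE_star": mu_star, "error": ""})
        emit("critical_mu_EE", pd.DataFrame(rows))
        scan = opts.get("mu_EE_scan")
        if scan:
            srows = []
            for mu in np.linspace(scan[0], scan[1], int(scan[2]) if len(scan) > 2 else 13):
                try:
                    fp = steady_state(params.with_(mu_EE=mu), conn, h, baseline_E, baseline_I)
                    J = jacobian(params.with_(mu_EE=mu), conn, h,
                                 active_E=fp[2], active_I=fp[3])
                    srows.append({"mu_EE": mu, "abscissa": spectral_abscissa(J)})
                except RuntimeError:
                    srows.append({"mu_EE": mu, "abscissa": np.nan})
            emit("abscissa_scan", pd.DataFrame(srows))

    elif scenario == "fc_sc":
        method = opts.get("method", "analytic")
        if method == "analytic":
            fc = analytic_fc(params, conn, h, noise_E, noise_I, baseline_E, baseline_I)
        else:
            duration_s = float(opts.get("duration_s", 120.0))
            fp = steady_state(params, conn, h, baseline_E, baseline_I)
            proto = InputProtocol(baseline_E=baseline_E, baseline_I=baseline_I,
                                  noise_sd_E=noise_E, noise_sd_I=noise_I, seed=seed)
            traj = simulate(params, conn, h, proto,
                            duration=duration_s * 1000.0,
                            dt=float(opts.get("dt_ms", 0.5)),
                            r0_E=fp[0], r0_I=fp[1])
            fc = empirical_fc(traj, discard_ms=2000.0)
        scope = opts.get("scope", "per_area" if conn.subnet is None else "by_subnet")
        report = fc_sc_dissimilarity(fc, conn, scope=scope,
                                     sc_transform=opts.get("sc_transform", "raw"))
        emit("fc_matrix", pd.DataFrame(report.fc, index=conn.areas, columns=conn.areas).reset_index())
        per = pd.DataFrame({"area": conn.areas, "dissimilarity": report.per_area})
        emit("per_area_dissimilarity", per)
        if report.subnet_summary is not None:
            emit("subnet_summary", report.subnet_summary)
        (out / "fc_sc_summary.json").write_text(json.dumps({
            "rho_global": report.rho_global,
            "dissimilarity_global": report.dissimilarity_global,
            "settings": report.settings,
        }, indent=2))
        outputs["fc_sc_summary"] = "fc_sc_summary.json"

    manifest = {
        "package_version": __version__,
        "scenario": scenario,
        "seed": seed,
        "config": _jsonable(config),
        "params": dataclasses.asdict(params),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16],
        "n_areas": conn.n_areas,
        "outputs": outputs,
        "wall_clock_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
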