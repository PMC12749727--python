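#!/usr/bin/env python
"""Structure-function coupling and its gradient/criticality dependence.

Computes functional connectivity from the stationary covariance of the
linearized network (Lyapunov route), compares it with the FLN-based
structural connectivity, and maps how the FC-SC dissimilarity 1 - |rho|
depends on the gradient slope (both manipulation modes), on each area's
position in the gradient, and on the long-range coupling's distance to
its critical value.

Writes results/fc_sc_gamma.csv, results/fc_sc_per_area.csv and
results/fc_sc_criticality.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from hiertime import (
    ModelParams,
    SyntheticSpec,
    analytic_fc,
    critical_coupling,
    fc_sc_dissimilarity,
    scale_gradient,
    synth_connectome,
)
from hiertime.gradient import GradientVector

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    params = ModelParams()
    conn = synth_connectome(SyntheticSpec(seed=SEED))
    h = GradientVector(conn.h_true)

    rows = []
    for mode in ("plain", "mean_preserving"):
        for gamma in np.linspace(0, 1, 6):
            fc = analytic_fc(params, conn, scale_gradient(h, gamma, mode))
            rep = fc_sc_dissimilarity(fc, conn)
            rows.append({"mode": mode, "gamma": gamma,
                         "dissimilarity": rep.dissimilarity_global})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "fc_sc_gamma.csv", index=False, float_format="%.6g")
    for mode in ("plain", "mean_preserving"):
        d = df[df["mode"] == mode]
        print(f"dissimilarity vs gamma ({mode}): "
              f"{d.dissimilarity.iloc[0]:.3f} -> {d.dissimilarity.iloc[-1]:.3f} "
              "(steeper gradient decouples FC from SC)")

    fc1 = analytic_fc(params, conn, h)
    per1 = fc_sc_dissimilarity(fc1, conn, scope="per_area").per_area
    fc0 = analytic_fc(params, conn, scale_gradient(h, 0.0))
    per0 = fc_sc_dissimilarity(fc0, conn, scope="per_area").per_area
    pd.DataFrame({"area": conn.areas, "h": h.h,
                  "dissimilarity_gamma1": per1,
                  "dissimilarity_gamma0": per0}).to_csv(
        RESULTS / "fc_sc_per_area.csv", index=False, float_format="%.6g")
    rho1 = stats.spearmanr(per1, h.h).statistic
    rho0 = stats.spearmanr(per0, h.h).statistic
    print(f"per-area dissimilarity vs gradient rank: Spearman {rho1:.2f} at "
          f"gamma=1, {rho0:.2f} at gamma=0 (association-like areas decouple "
          "most, only when the gradient is present)")

    h0 = scale_gradient(h, 0.0)
    mu_star = critical_coupling(params, conn, h0, knob="mu_EE")
    rows = []
    for lam in np.linspace(0.93, 0.995, 10):
        fc = analytic_fc(params.with_(mu_EE=lam * mu_star), conn, h0)
        rows.append({"lambda": lam, "mu_EE": lam * mu_star,
                     "dissimilarity":
                         fc_sc_dissimilarity(fc, conn).dissimilarity_global})
    dfc = pd.DataFrame(rows)
    dfc.to_csv(RESULTS / "fc_sc_criticality.csv", index=False,
               float_format="%.6g")
    print(f"approach to criticality (mu*_EE = {mu_star:.2f} pA/Hz): "
          f"dissimilarity {dfc.dissimilarity.iloc[0]:.3f} -> "
          f"{dfc.dissimilarity.iloc[-1]:.3f} as mu_EE -> mu*_EE")
    return 0


if __name__ == "__main__":
    sys.exit(main())
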