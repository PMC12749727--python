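#!/usr/bin/env python
"""Signal propagation from a sensory area and its structural requirements.

Applies a 200 ms pulse to the lowest-gradient (sensory-like) area from the
resting fixed point and records every area's peak response, then repeats
the experiment with all feedback projections deleted (FLN zeroed where
SLN < 0.5) and with the excitation gradient removed.

Writes results/pulse_peaks.csv and results/propagation_conditions.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from hiertime import (
    ModelParams,
    SyntheticSpec,
    compare_conditions,
    pulse_response,
    remove_feedback,
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
    target = conn.areas[int(np.argmin(h.h))]

    kw = dict(amplitude=20.0, duration=200.0, record_ms=2200.0, dt=0.25)
    base = pulse_response(params, conn, h, target, condition="control", **kw)
    base.table.to_csv(RESULTS / "pulse_peaks.csv", index=False,
                      float_format="%.6g")
    print(f"pulse to {target} (20 pA, 200 ms): peak responses "
          f"{base.peaks.min():.2g}-{base.peaks.max():.2g} Hz across "
          f"{conn.n_areas} areas")

    variants = [
        pulse_response(params, remove_feedback(conn), h, target,
                       condition="feedback_removed", **kw),
        pulse_response(params, conn, scale_gradient(h, 0.0), target,
                       condition="gradient_removed", **kw),
    ]
    cmp_df = compare_conditions(base, variants)
    cmp_df.to_csv(RESULTS / "propagation_conditions.csv", index=False,
                  float_format="%.6g")
    for cond in ("feedback_removed", "gradient_removed"):
        mlr = cmp_df.loc[cmp_df.condition == cond, "mean_log_ratio"].iloc[0]
        print(f"{cond}: mean log peak ratio {mlr:.2f} "
              f"({'generalized decrease' if mlr < 0 else 'increase'} vs control)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
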