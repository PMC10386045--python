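"""Scripted drug-injection scenario through the full pipeline.

A two-region phantom is imaged at t = 0 and t = 20 min; at 20 min the tumor
pH is scripted to drop by 0.31 units (an NHE1-inhibitor-like intracellular
acidification).  The pipeline simulates, processes and maps both
timepoints, then reports region time courses with percent AACID change and
the ΔpH implied by the linear calibration.  Outputs land in
scratch/scenario/ (maps, CSVs, provenance log).
"""

from pathlib import Path

import pandas as pd

import aacidcest as ac
from aacidcest.io import RunConfig

spec = ac.PhantomSpec(
    nx=10,
    ny=10,
    classes=(
        ac.TissueClass("contralateral", ph=7.0),
        ac.TissueClass("tumor", ph=7.3, shape=("ellipse", 0.45, 0.5, 0.3, 0.35)),
    ),
    noise_sigma=0.0,
    seed=8,
)
config = RunConfig(
    phantom=spec,
    n_repeats=1,
    timepoints={0.0: {}, 20.0: {"tumor": 6.99}},
    smoothing=0,
    seed=8,
)

out = ac.run_pipeline(config, Path("scratch/scenario"))
table = pd.read_csv(out / "roi_results.csv")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("tumor AACID rises when the scripted pH falls (inverse relation);")
print("delta_ph is the calibrated -4*dAACID conversion vs the t=0 baseline.")
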