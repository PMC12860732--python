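"""Ablation harness: rerun the protocol with one component disabled.

Each row reports the ensemble metric with the component removed minus the
full configuration (negative delta = the component was helping).
"""

import warnings

from softvote import ExperimentConfig, GeneratorConfig
from softvote.experiment import run_ablation, run_experiment

warnings.filterwarnings("ignore")

cfg = ExperimentConfig(generator=GeneratorConfig(n_docs=1200, seed=9), k=2, seed=9)
base = run_experiment(cfg)

for key in ("uniform_fusion", "no_class_weights", "fixed_threshold_0.5"):
    result = run_ablation(cfg, key, base_report=base)
    d = result["deltas"]["macro_f1"]
    dm = result["deltas"]["minority_macro_f1"]
    print(
        f"{key:22s} macro-F1 delta {d['delta_mean']:+.4f}  "
        f"minority delta {dm['delta_mean']:+.4f}"
    )
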