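#!/usr/bin/env python
"""Robustness checks of the classification pipeline.

1. SIMCA held-out accuracy under Savitzky-Golay windows 7/11/15 channels.
2. Held-out accuracy as the global freeze-thaw effect size is scaled over
   {0, 0.5, 1, 2} (averaged over 5 generator seeds).
3. The null scenario (no class effects): both classifiers fall to chance.

Writes results/robustness.json.
"""

import json
from pathlib import Path

import numpy as np

from freezenir.metrics import build_confusion, total_accuracy
from freezenir.plsda import fit_plsda, predict_plsda
from freezenir.preprocess import PreprocessConfig
from freezenir.simca import classify, fit_simca
from freezenir.spectra_io import split_calibration_validation
from freezenir.synthdata import default_config, generate, null_config, scale_effects

OUT = Path(__file__).resolve().parent.parent / "results"


def holdout_accuracy(data, seed, method="simca", pretreatment=None):
    split = split_calibration_validation(data, 2 / 3, seed=seed)
    if method == "simca":
        model = fit_simca(split.calibration, pretreatment=pretreatment)
        result = classify(model, split.validation)
    else:
        model = fit_plsda(split.calibration, pretreatment=pretreatment)
        result = predict_plsda(model, split.validation)
    return total_accuracy(build_confusion(split.validation.labels, result))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out = {}

    data = generate(default_config(n_per_class=100, seed=1))
    out["sg_window_sweep"] = {
        str(w): round(
            holdout_accuracy(data, 1, pretreatment=PreprocessConfig(sg_window=w)), 1
        )
        for w in (7, 11, 15)
    }
    print("SIMCA validation accuracy by SG window:", out["sg_window_sweep"])

    dial = {}
    for mult in (0.0, 0.5, 1.0, 2.0):
        accs = [
            holdout_accuracy(
                generate(scale_effects(default_config(n_per_class=30, seed=s), mult)), s
            )
            for s in range(1, 6)
        ]
        dial[str(mult)] = round(float(np.mean(accs)), 1)
    out["effect_size_dial"] = dial
    print("SIMCA accuracy vs effect multiplier:", dial)

    null_data = generate(null_config(default_config(n_per_class=60, seed=1)))
    out["null_scenario"] = {
        m: round(holdout_accuracy(null_data, 1, method=m), 1)
        for m in ("simca", "plsda")
    }
    print("null-scenario accuracies:", out["null_scenario"])

    with open(OUT / "robustness.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    print(f"\nwrote {OUT / 'robustness.json'}")


if __name__ == "__main__":
    main()
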