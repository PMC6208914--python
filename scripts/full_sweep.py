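"""Opt-in long-running experiment: the full fit-and-score sweep.

Fits LN models for every included variant of both model classes under all
three noise regimes and five synaptic weights, at the full 20-point
working-point grid with 1024 trials per transfer-function frequency, then
scores each condition with the 4096-neuron / 5-seed stepped-Poisson test
and reports, per class, the fraction of conditions reaching
Er_opt >= 0.8.  This is a multi-hour computation on one CPU; the test
suite instead runs the reduced sweep in tests/test_acceptance.py.

Usage:  python scripts/full_sweep.py --seed 1 --out results/full_sweep
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from lnrate.evaluate import sweep_er_opt
from lnrate.io import records_dataframe
from lnrate.lnmodel import WORKING_POINTS
from lnrate.neuron_models import list_variants


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/full_sweep"))
    ap.add_argument("--classes", nargs="+",
                    default=["amat", "izhikevich"])
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    weights = {"izhikevich": [0.1, 0.25, 0.5, 0.6, 0.75],
               "amat": [100.0, 300.0, 500.0, 700.0, 900.0]}
    for model_class in args.classes:
        summary, fits, acts, records = sweep_er_opt(
            model_class, list_variants(model_class),
            weights=weights[model_class],
            working_points=WORKING_POINTS,
            a0_grid=np.arange(0.0, 1001.0, 10.0),
            activation_duration=10_000.0, equilibration=1000.0,
            tf_trials=1024, n_starts=60, n_starts_lowpass=15,
            n_neurons=4096, n_seeds=5, seed=args.seed)
        summary.to_csv(args.out / f"{model_class}_summary.csv", index=False)
        records_dataframe(records).to_csv(
            args.out / f"{model_class}_stepped_records.csv", index=False)
        frac = np.mean(np.nan_to_num(summary.er_opt.to_numpy()) >= 0.8)
        print(f"{model_class}: fraction of conditions with Er_opt >= 0.8: "
              f"{100 * frac:.0f}%")


if __name__ == "__main__":
    main()
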