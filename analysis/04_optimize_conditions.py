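#!/usr/bin/env python
"""Search for the extraction conditions maximizing the four responses.

Runs the real-coded genetic algorithm over both surrogates (the fitted
quadratics and, when 02 has been run, the saved neural surrogate) with
equal response weights, and verifies the quadratic-surface optimum against
an exhaustive 21^4 lattice search.  Writes results/optimum_rsm.json,
results/optimum_ann.json and results/ga_trace_rsm.csv.
"""

import json
from pathlib import Path

import numpy as np

from extractopt.ann import load_surrogate, predict_ann
from extractopt.design import TABLE1_FACTORS, code_value
from extractopt.optimize import GaConfig, ga_optimize, grid_search_oracle
from extractopt.rsm import fit_quadratic, predict
from extractopt.synthetic import RESPONSE_NAMES, load_table1_fixture

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design, observed, _, _ = load_table1_fixture()
    responses = observed[list(RESPONSE_NAMES)]
    models = {r: fit_quadratic(design, responses[r], r) for r in RESPONSE_NAMES}

    cfg = GaConfig(
        factors=TABLE1_FACTORS,
        weights=(1.0, 1.0, 1.0, 1.0),
        norm_min=tuple(responses.min()),
        norm_max=tuple(responses.max()),
        seed=SEED,
        seed_points=tuple(map(tuple, design.coded().values)),
    )

    def rsm_fn(points):
        return np.column_stack([predict(models[r], points) for r in RESPONSE_NAMES])

    res = ga_optimize(rsm_fn, cfg)
    _, oracle_fit = grid_search_oracle(rsm_fn, cfg, resolution=21)
    res.trace.to_csv(OUT / "ga_trace_rsm.csv")
    (OUT / "optimum_rsm.json").write_text(json.dumps({
        "best_settings": res.best_actual,
        "predicted": dict(zip(RESPONSE_NAMES, res.predicted.values())),
        "fitness": res.fitness,
        "grid_oracle_fitness": oracle_fit,
    }, indent=1))
    print("quadratic-surface optimum (equal weights):")
    print("  " + ", ".join(f"{k}={v:.2f}" for k, v in res.best_actual.items()))
    print(f"  fitness {res.fitness:.4f}; 21^4 lattice oracle {oracle_fit:.4f} "
          f"(gap {oracle_fit - res.fitness:+.5f})")

    surrogate_path = OUT / "ann_surrogate.json"
    if surrogate_path.exists():
        surrogate = load_surrogate(surrogate_path)

        def ann_fn(points):
            coded = np.column_stack([
                code_value(f, points[f.name].values.astype(float), "affine")
                for f in TABLE1_FACTORS
            ])
            return predict_ann(surrogate, coded, warn_off_box=False).values

        res_ann = ga_optimize(ann_fn, cfg)
        (OUT / "optimum_ann.json").write_text(json.dumps({
            "best_settings": res_ann.best_actual,
            "predicted": dict(zip(RESPONSE_NAMES, res_ann.predicted.values())),
            "fitness": res_ann.fitness,
        }, indent=1))
        print("\nneural-surrogate optimum (equal weights):")
        print("  " + ", ".join(f"{k}={v:.2f}" for k, v in res_ann.best_actual.items()))
        print(f"  fitness {res_ann.fitness:.4f}")
    else:
        print("\n(run 02_train_ann_surrogate.py first for the neural-surrogate search)")


if __name__ == "__main__":
    main()
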