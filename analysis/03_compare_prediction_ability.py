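#!/usr/bin/env python
"""Compare response-surface and neural predictions by AAD, SEP, RMSE and R^2.

Two comparisons are reported:

1. the two prediction columns published alongside the experimental data —
   on those, the neural surrogate beats the response surface on every
   metric for every response;
2. this package's own fitted quadratic vs its own trained surrogate.

Writes results/comparison_published.csv and results/comparison_refit.csv
(with matching *_verdicts.csv).
"""

from pathlib import Path

import pandas as pd

from extractopt.ann import load_surrogate, predict_ann
from extractopt.metrics import compare_models
from extractopt.rsm import fit_quadratic, predict
from extractopt.synthetic import RESPONSE_NAMES, load_table1_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design, observed, rsm_pred, ann_pred = load_table1_fixture()
    responses = observed[list(RESPONSE_NAMES)]

    grid, verdicts = compare_models(responses, rsm_pred, ann_pred)
    grid.to_csv(OUT / "comparison_published.csv")
    verdicts.to_csv(OUT / "comparison_published_verdicts.csv")
    print("published prediction columns:")
    print(grid.round(3))
    print("\nbetter model per response/metric:")
    print(verdicts)

    surrogate_path = OUT / "ann_surrogate.json"
    if surrogate_path.exists():
        surrogate = load_surrogate(surrogate_path)
        own_ann = predict_ann(surrogate, design)
        own_rsm = pd.DataFrame(
            {r: predict(fit_quadratic(design, responses[r], r), design.actual)
             for r in RESPONSE_NAMES},
            index=design.actual.index,
        )
        grid2, verdicts2 = compare_models(responses, own_rsm, own_ann)
        grid2.to_csv(OUT / "comparison_refit.csv")
        verdicts2.to_csv(OUT / "comparison_refit_verdicts.csv")
        print("\nre-fitted surrogates (this package's own models):")
        print(grid2.round(3))
    else:
        print("\n(run 02_train_ann_surrogate.py first for the re-fitted comparison)")


if __name__ == "__main__":
    main()
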