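"""Synthetic Box-Behnken studies with known ground truth, and the packaged
27-run seaweed-extraction dataset.

The generator draws responses from a known full-quadratic surface evaluated
at the coded design points plus i.i.d. Gaussian noise, so coefficient
recovery, confidence-interval coverage and surrogate behaviour can all be
checked against a truth the analysis never sees.  A "study-like" preset uses
the total-phenolic-content surface fitted to the packaged dataset as truth,
with the noise SD chosen so the signal-to-noise variance ratio is about 10 —
the regime in which fitted R² lands in the low 0.9s, matching the packaged
study.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import TABLE1_FACTORS, DesignTable, FactorSpec, build_bbd
from .rsm import fit_quadratic, model_matrix, term_names

__all__ = [
    "GroundTruth",
    "generate_study",
    "study_like_truth",
    "load_table1_fixture",
    "RESPONSE_NAMES",
]

RESPONSE_NAMES = ("tpc", "tfc", "dpph", "abts")

_FIXTURE_SHA256 = "3be290fa17229f01cb83683563700743ca1c9a304983eee75fcad1587611cb19"


@dataclass(frozen=True)
class GroundTruth:
    """True coded-scale quadratic coefficients and noise level per response."""

    coef: pd.DataFrame  # index = term names, one column per response
    noise_sd: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name!r}] must be >= 0")

    @property
    def response_names(self) -> list[str]:
        return list(self.coef.columns)


def generate_study(
    factors: tuple[FactorSpec, ...],
    truth: GroundTruth,
    n_center: int = 3,
    scheme: str = "affine",
) -> tuple[DesignTable, pd.DataFrame]:
    """BBD responses from the true surface plus seeded Gaussian noise."""
    design = build_bbd(factors, n_center=n_center, scheme=scheme)
    expected = term_names([f.name for f in factors])
    if list(truth.coef.index) != expected:
        raise ValueError(
            "ground-truth coefficient index does not match the factor set's "
            f"term names (expected {len(expected)} terms)"
        )
    X = model_matrix(design.coded())
    rng = np.random.default_rng(truth.seed)
    out = {}
    for resp in truth.response_names:
        mean = X[truth.coef.index].values @ truth.coef[resp].values
        out[resp] = mean + rng.normal(0.0, truth.noise_sd[resp], size=len(mean))
    return design, pd.DataFrame(out, index=design.actual.index)


def study_like_truth(seed: int = 0, snr: float = 10.0) -> GroundTruth:
    """Ground truth whose surface is the fixture's fitted TPC model.

    The noise SD is set so the variance of the true surface over the design
    points is ``snr`` times the noise variance.
    """
    design, responses, _, _ = load_table1_fixture()
    model = fit_quadratic(design, responses["tpc"], "tpc")
    X = model_matrix(design.coded())
    surface = X[model.coef.index].values @ model.coef.values
    sd = float(np.std(surface, ddof=0) / np.sqrt(snr))
    coef = pd.DataFrame({"tpc": model.coef})
    return GroundTruth(coef=coef, noise_sd={"tpc": sd}, seed=seed)


def load_table1_fixture(
    scheme: str = "affine",
) -> tuple[DesignTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The packaged 27-run study: design, observed responses (with SDs) and
    the two published prediction columns (response-surface and neural).

    The observed frame carries ``<resp>`` and ``<resp>_sd`` columns; the SDs
    are replicate spreads of the assay triplicates and are not used by the
    fits, which model the run means.
    """
    ref = resources.files("extractopt").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged dataset is corrupted (sha256 {digest[:12]}..., "
            f"expected {_FIXTURE_SHA256[:12]}...)"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw)).set_index("run_id")
    design = DesignTable(
        TABLE1_FACTORS, df[[f.name for f in TABLE1_FACTORS]], scheme
    )
    observed = df[
        [c for r in RESPONSE_NAMES for c in (r, f"{r}_sd")]
    ].copy()
    rsm_pred = df[[f"{r}_rsm" for r in RESPONSE_NAMES]].rename(
        columns=lambda c: c[:-4]
    )
    ann_pred = df[[f"{r}_ann" for r in RESPONSE_NAMES]].rename(
        columns=lambda c: c[:-4]
    )
    return design, observed, rsm_pred, ann_pred
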