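"""Box-Behnken designs and the mapping between actual and coded factor levels.

A Box-Behnken design (BBD) for k three-level factors runs, for every pair of
factors, the four (+-1, +-1) corner combinations with all remaining factors at
their center level, plus a block of replicated all-center runs.  The center
replicates supply the pure-error estimate needed by the lack-of-fit test.

Two coding schemes are supported.  ``ordinal`` maps the (low, center, high)
levels to (-1, 0, +1) by level index, regardless of spacing.  ``affine``
rescales linearly so that the low and high levels map to -1 and +1; a center
level that is not the midpoint of low and high (e.g. an ultrasonic frequency
of 35 kHz between 26 and 40 kHz) then codes to a nonzero interior value.
The two schemes produce different interaction and curvature columns whenever
a factor's levels are unequally spaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CODING_SCHEMES = ("ordinal", "affine")


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three design levels in actual units."""

    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r}: exactly 3 levels required")
        lo, mid, hi = self.levels
        if not (lo < mid < hi):
            raise ValueError(
                f"factor {self.name!r}: levels must be distinct and strictly "
                f"increasing, got {self.levels}"
            )
        if not self.unit:
            raise ValueError(f"factor {self.name!r}: unit must be non-empty")

    @property
    def low(self) -> float:
        return self.levels[0]

    @property
    def center(self) -> float:
        return self.levels[1]

    @property
    def high(self) -> float:
        return self.levels[2]


#: Factor specifications of the packaged 27-run seaweed-extraction study:
#: ethanol concentration, sonication time, bath temperature and ultrasonic
#: frequency.  The frequency levels are unequally spaced.
TABLE1_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("ethanol_pct", "%", (30.0, 50.0, 70.0)),
    FactorSpec("time_min", "min", (20.0, 35.0, 50.0)),
    FactorSpec("temperature_C", "degC", (20.0, 40.0, 60.0)),
    FactorSpec("frequency_kHz", "kHz", (26.0, 35.0, 40.0)),
)


def code_value(factor: FactorSpec, actual: float | np.ndarray, scheme: str = "affine"):
    """Map actual factor values to the coded scale.

    ``ordinal`` requires the value to sit exactly on one of the three design
    levels and returns the level index shifted to {-1, 0, +1}.  ``affine``
    applies v -> (v - (low+high)/2) / ((high-low)/2) and accepts any value.
    """
    _check_scheme(scheme)
    lo, mid, hi = factor.levels
    v = np.asarray(actual, dtype=float)
    if scheme == "affine":
        coded = (v - (lo + hi) / 2.0) / ((hi - lo) / 2.0)
    else:
        coded = np.select(
            [np.isclose(v, lo), np.isclose(v, mid), np.isclose(v, hi)],
            [-1.0, 0.0, 1.0],
            default=np.nan,
        )
        if np.any(np.isnan(coded)):
            bad = np.asarray(v)[np.isnan(coded)]
            raise ValueError(
                f"factor {factor.name!r}: value(s) {bad} are not design levels "
                f"{factor.levels}; ordinal coding requires on-level values"
            )
    return float(coded) if np.isscalar(actual) else coded


def decode_value(factor: FactorSpec, coded: float | np.ndarray, scheme: str = "affine"):
    """Inverse of :func:`code_value`.

    Under ``ordinal`` the coded value is snapped to the nearest of {-1, 0, +1}
    and mapped back to the corresponding design level (only the three physical
    levels exist).  Under ``affine`` the linear map is inverted exactly.
    """
    _check_scheme(scheme)
    lo, mid, hi = factor.levels
    c = np.asarray(coded, dtype=float)
    if scheme == "affine":
        actual = c * ((hi - lo) / 2.0) + (lo + hi) / 2.0
    else:
        idx = np.clip(np.rint(c), -1, 1).astype(int) + 1
        actual = np.asarray(factor.levels, dtype=float)[idx]
    return float(actual) if np.isscalar(coded) else actual


@dataclass
class DesignTable:
    """A design in actual units together with its coded representation."""

    factors: tuple[FactorSpec, ...]
    actual: pd.DataFrame  # index run_id, one column per factor, actual units
    scheme: str = "affine"
    is_center: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_scheme(self.scheme)
        self.factors = tuple(self.factors)
        names = [f.name for f in self.factors]
        self.actual = self.actual[names].astype(float)
        self.actual.index.name = "run_id"
        if self.is_center is None:
            centers = np.array([f.center for f in self.factors])
            self.is_center = pd.Series(
                np.all(np.isclose(self.actual.values, centers), axis=1),
                index=self.actual.index,
                name="is_center",
            )

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.actual)

    def coded(self, scheme: str | None = None) -> pd.DataFrame:
        """Per-run coded levels under this table's (or an overriding) scheme."""
        scheme = self.scheme if scheme is None else scheme
        out = {}
        for f in self.factors:
            out[f.name] = code_value(f, self.actual[f.name].values, scheme)
        return pd.DataFrame(out, index=self.actual.index)

    def with_scheme(self, scheme: str) -> "DesignTable":
        return DesignTable(self.factors, self.actual.copy(), scheme, self.is_center)


def build_bbd(
    factors: Sequence[FactorSpec],
    n_center: int = 3,
    scheme: str = "affine",
) -> DesignTable:
    """Construct the standard Box-Behnken design for 3-5 factors.

    For every pair (i, j) of factors the four combinations with factors i and
    j at (+-1, +-1) and every other factor at its center are generated, in
    pair-major order ((-1,-1), (+1,-1), (-1,+1), (+1,+1)); ``n_center``
    all-center replicates follow.  Run ids are 1..n in that canonical order.
    """
    k = len(factors)
    if k not in (3, 4, 5):
        raise ValueError(f"supported factor counts are 3-5, got {k}")
    if n_center < 1:
        raise ValueError("at least one center run is required")

    rows = []
    for i, j in combinations(range(k), 2):
        for sj, si in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
            row = [f.center for f in factors]
            row[i] = factors[i].low if si < 0 else factors[i].high
            row[j] = factors[j].low if sj < 0 else factors[j].high
            rows.append(row)
    for _ in range(n_center):
        rows.append([f.center for f in factors])

    actual = pd.DataFrame(
        rows,
        columns=[f.name for f in factors],
        index=pd.RangeIndex(1, len(rows) + 1, name="run_id"),
    )
    return DesignTable(tuple(factors), actual, scheme)


def validate_design(table: DesignTable, lack_of_fit: bool = False) -> list[str]:
    """Check BBD structural invariants; returns human-readable violations.

    Never raises: every problem is reported as one entry naming the run and
    the rule it breaks.  With ``lack_of_fit=True`` a warning entry is added
    when fewer than 3 center replicates are present.
    """
    violations: list[str] = []
    for f in table.factors:
        vals = table.actual[f.name].values
        on_level = np.isclose(vals[:, None], np.asarray(f.levels)[None, :]).any(axis=1)
        for run_id in table.actual.index[~on_level]:
            violations.append(
                f"run {run_id}: factor {f.name!r} value "
                f"{table.actual.at[run_id, f.name]} is not one of levels {f.levels}"
            )
    if violations:
        return violations  # coded pattern checks assume on-level values

    coded = table.coded("ordinal")
    n_extreme = (coded.abs().values > 0.5).sum(axis=1)
    for run_id, n_ext, center in zip(
        table.actual.index, n_extreme, table.is_center.values
    ):
        if center and n_ext != 0:
            violations.append(f"run {run_id}: flagged center but has coded +-1 factors")
        elif not center and n_ext != 2:
            violations.append(
                f"run {run_id}: non-center run has {n_ext} factors at +-1 "
                "(a BBD run sets exactly two)"
            )
    if lack_of_fit and int(table.is_center.sum()) < 3:
        violations.append(
            f"design: only {int(table.is_center.sum())} center replicates; "
            ">=3 recommended when a lack-of-fit test is requested"
        )
    return violations


def coded_pattern_multiset(table: DesignTable) -> list[tuple[float, ...]]:
    """Sorted list of ordinal coded patterns; order-free design comparison."""
    pats = [tuple(row) for row in table.coded("ordinal").values.round(0)]
    return sorted(pats)


def load_design_csv(
    path, factors: Sequence[FactorSpec], scheme: str = "affine"
) -> DesignTable:
    """Read a design from CSV with a ``run_id`` column plus one per factor."""
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise ValueError("design CSV requires a 'run_id' column")
    missing = [f.name for f in factors if f.name not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing factor column(s): {missing}")
    df = df.set_index("run_id")
    return DesignTable(tuple(factors), df, scheme)


def _check_scheme(scheme: str) -> None:
    if scheme not in CODING_SCHEMES:
        raise ValueError(f"unknown coding scheme {scheme!r}; use one of {CODING_SCHEMES}")
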