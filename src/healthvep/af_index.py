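"""Alkire-Foster multidimensional health-poverty scoring.

Three steps: (1) map raw survey fields to binary deprivations via per-indicator
rules, (2) weight and sum into a deprivation score in [0, 1], (3) classify as
poor when the score reaches the cutoff ``gamma`` (boundary inclusive).

Two built-in indicator systems are provided: a 7-indicator physical-health
index and a 10-indicator mental-health index, each with equal weights and
indicators organised into predisposing / enabling / need dimensions.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

DIMENSIONS = ("predisposing", "enabling", "need")
#: deprivation rules: how a raw field maps to {0, 1}
#:   absent     -> deprived when the (binary, 1 = yes/has) field is 0
#:   present    -> deprived when the binary field is 1
#:   score_high -> deprived when a 1-4 psychometric score is 3 or 4
RULES = ("absent", "present", "score_high")


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    dimension: str
    weight: float
    field: str
    rule: str

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight must lie in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class DeprivationProfile:
    indicator_values: tuple[int, ...]
    weighted_score: float
    poor: int


def builtin_specs() -> tuple[list[IndicatorSpec], list[IndicatorSpec]]:
    """The built-in physical (7 x 1/7) and mental (10 x 1/10) indicator sets."""
    w7, w10 = 1.0 / 7.0, 1.0 / 10.0
    php = [
        IndicatorSpec("health_insurance", "enabling", w7, "health_insurance", "absent"),
        IndicatorSpec("chronic_illness", "need", w7, "chronic_illness", "present"),
        IndicatorSpec("bronchitis", "need", w7, "bronchitis", "present"),
        IndicatorSpec("asthma", "need", w7, "asthma", "present"),
        IndicatorSpec("hospitalization", "need", w7, "hospitalized", "present"),
        IndicatorSpec("health_status", "need", w7, "unwell", "present"),
        IndicatorSpec("work_strain", "predisposing", w7, "weekend_break", "absent"),
    ]
    mhp = [IndicatorSpec("health_insurance", "enabling", w10, "health_insurance", "absent")]
    for item in ("depression", "struggle", "poor_sleep", "unpleasant",
                 "lonely", "sad", "difficulty", "hopeless"):
        mhp.append(IndicatorSpec(item, "need", w10, item, "score_high"))
    mhp.append(IndicatorSpec("social_relationship", "predisposing", w10,
                             "social_relationship", "absent"))
    return php, mhp


def check_weights(spec: Sequence[IndicatorSpec]) -> None:
    total = sum(s.weight for s in spec)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"indicator weights must sum to 1, got {total!r}")


def _apply_rule(values: np.ndarray, rule: str, name: str) -> np.ndarray:
    if rule == "absent":
        _check_binary(values, name)
        return (values == 0).astype(int)
    if rule == "present":
        _check_binary(values, name)
        return (values == 1).astype(int)
    # score_high: 1-4 psychometric scale only; out-of-range is an error
    out = (values < 1) | (values > 4)
    if out.any():
        row = int(np.argmax(out))
        raise ValueError(f"indicator {name!r}: score {values[row]!r} at row {row} "
                         f"outside the 1-4 scale")
    return (values >= 3).astype(int)


def _check_binary(values: np.ndarray, name: str) -> None:
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        row = int(np.argmax(bad))
        raise ValueError(f"indicator {name!r}: value {values[row]!r} at row {row} "
                         f"is not binary")


def apply_deprivations(records: pd.DataFrame | pd.Series,
                       spec: Sequence[IndicatorSpec]) -> np.ndarray:
    """Binary deprivation matrix, one column per indicator in ``spec``.

    Accepts a table (rows x indicators result) or a single record (1-d result).
    """
    single = isinstance(records, pd.Series)
    frame = records.to_frame().T if single else records
    columns = []
    for s in spec:
        if s.field not in frame.columns:
            raise KeyError(f"record lacks field {s.field!r} required by "
                           f"indicator {s.name!r}")
        columns.append(_apply_rule(frame[s.field].to_numpy(), s.rule, s.name))
    matrix = np.column_stack(columns) if columns else np.empty((len(frame), 0), int)
    return matrix[0] if single else matrix


def weighted_scores(indicator_values: np.ndarray,
                    spec: Sequence[IndicatorSpec]) -> np.ndarray:
    """Row-wise weighted deprivation score(s) in [0, 1]."""
    values = np.atleast_2d(np.asarray(indicator_values))
    if values.shape[1] != len(spec):
        raise ValueError(f"got {values.shape[1]} indicator values for "
                         f"{len(spec)} indicators")
    check_weights(spec)
    weights = np.array([s.weight for s in spec])
    scores = values @ weights
    return scores if np.asarray(indicator_values).ndim == 2 else scores[0]


def score_and_classify(indicator_values: Iterable[int],
                       spec: Sequence[IndicatorSpec],
                       gamma: float = 0.30) -> DeprivationProfile:
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    values = np.asarray(list(indicator_values), int)
    score = float(weighted_scores(values, spec))
    return DeprivationProfile(tuple(int(v) for v in values), score,
                              int(score >= gamma))


def classify_table(records: pd.DataFrame, spec: Sequence[IndicatorSpec],
                   gamma: float = 0.30) -> pd.DataFrame:
    """Per-row weighted score and poor flag for a whole table."""
    matrix = apply_deprivations(records, spec)
    scores = weighted_scores(matrix, spec)
    return pd.DataFrame({"score": scores, "poor": (scores >= gamma).astype(int)},
                        index=records.index)


def aggregate(profiles: Sequence[DeprivationProfile]) -> dict[str, float | None]:
    """Standard A-F aggregates over a list of profiles."""
    if not profiles:
        raise ValueError("aggregate requires a nonempty profile list")
    poor = np.array([p.poor for p in profiles])
    scores = np.array([p.weighted_score for p in profiles])
    headcount = float(poor.mean())
    if poor.sum() == 0:
        return {"headcount_ratio": 0.0, "mean_intensity_among_poor": None,
                "adjusted_headcount": 0.0}
    intensity = float(scores[poor == 1].mean())
    return {"headcount_ratio": headcount,
            "mean_intensity_among_poor": intensity,
            "adjusted_headcount": headcount * intensity}


def combine_scores(php: pd.DataFrame, mhp: pd.DataFrame, rule: str = "either",
                   gamma: float = 0.30) -> pd.DataFrame:
    """Merge the physical and mental classifications into one joint status.

    rule "either": poor in at least one index (default); "both": poor in both;
    "score-union": mean of the two scores re-thresholded at gamma.  The joint
    ``score`` column is always the mean of the two index scores and feeds the
    welfare mapping of the vulnerability stage.
    """
    score = 0.5 * (php["score"] + mhp["score"])
    if rule == "either":
        poor = ((php["poor"] == 1) | (mhp["poor"] == 1)).astype(int)
    elif rule == "both":
        poor = ((php["poor"] == 1) & (mhp["poor"] == 1)).astype(int)
    elif rule == "score-union":
        poor = (score >= gamma).astype(int)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return pd.DataFrame({"score": score, "poor": poor}, index=php.index)


# -- spec (de)serialisation --------------------------------------------------

def specs_to_yaml(spec: Sequence[IndicatorSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(
        [dataclasses.asdict(s) for s in spec], sort_keys=False))


def specs_from_yaml(path: str | Path) -> list[IndicatorSpec]:
    raw = yaml.safe_load(Path(path).read_text())
    spec = [IndicatorSpec(**entry) for entry in raw]
    check_weights(spec)
    return spec
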