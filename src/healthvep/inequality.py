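"""Coefficient-of-variation and entropy (Theil T) inequality indices.

Both indices are scale-invariant, nonnegative, and zero exactly on constant
inputs.  The regional report computes each index within urban and rural
subsets of every region/province group and their urban-minus-rural gap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InequalityIndexResult:
    index_name: str  # "cv" | "theil_t"
    value: float | None
    grouping: str
    subset: str  # "urban" | "rural" | "gap" | "all"
    input_variable: str
    n: int
    missing: bool = False


def _check_positive(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("input vector is empty")
    if (v <= 0).any():
        raise ValueError("inequality indices require strictly positive values")
    return v


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    v = _check_positive(values)
    if v.size == 1 or np.ptp(v) == 0.0:
        return 0.0
    return float(v.std(ddof=1) / v.mean())


def theil_t(values) -> float:
    """Theil T entropy index: sum (x_i / sum x) * ln(x_i / mean)."""
    v = _check_positive(values)
    if np.ptp(v) == 0.0:
        return 0.0
    shares = v / v.sum()
    return float(np.sum(shares * np.log(v / v.mean())))


_INDICES = {"cv": coefficient_of_variation, "theil_t": theil_t}


def regional_gap_report(table: pd.DataFrame, value_column: str,
                        group_columns=("region",)) -> list[InequalityIndexResult]:
    """Both indices per group, within urban and rural subsets plus their gap.

    Groups (or urban/rural cells) with fewer than 2 observations are flagged
    missing rather than aborting the run.
    """
    for col in (value_column, "urban", *group_columns):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    results: list[InequalityIndexResult] = []
    for group_col in group_columns:
        for group, sub in table.groupby(group_col, sort=True):
            label = f"{group_col}={group}"
            values = {}
            for name, fn in _INDICES.items():
                for subset, mask in (("urban", sub["urban"] == 1),
                                     ("rural", sub["urban"] == 0)):
                    cell = sub.loc[mask, value_column]
                    if len(cell) < 2:
                        results.append(InequalityIndexResult(
                            name, None, label, subset, value_column,
                            len(cell), missing=True))
                        values[(name, subset)] = None
                    else:
                        val = fn(cell.to_numpy())
                        results.append(InequalityIndexResult(
                            name, val, label, subset, value_column, len(cell)))
                        values[(name, subset)] = val
                u, r = values[(name, "urban")], values[(name, "rural")]
                if u is None or r is None:
                    results.append(InequalityIndexResult(
                        name, None, label, "gap", value_column, len(sub),
                        missing=True))
                else:
                    results.append(InequalityIndexResult(
                        name, u - r, label, "gap", value_column, len(sub)))
    return results


def report_to_frame(results: list[InequalityIndexResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
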