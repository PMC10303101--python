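"""Pre-processing of a cohort table into the [0,1] matrix fed to the network.

Every variable is brought onto a common proportional scale before training:
either dichotomized (high/low around a split point, by default the cohort
median) or min–max scaled into [0,1]. Already-binary variables pass through
unchanged. Constant variables cannot be encoded and raise instead of being
silently folded in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable

__all__ = [
    "DegenerateVariableError",
    "VariableEncoding",
    "dichotomize",
    "minmax_scale",
    "encode_cohort",
    "default_encodings",
]


class DegenerateVariableError(ValueError):
    """A variable is constant (or otherwise unencodable) and must be dropped."""


@dataclass(frozen=True)
class VariableEncoding:
    """How one source variable is encoded: 'dichotomic' or 'minmax'."""

    source_variable: str
    mode: str = "dichotomic"
    split_value: float | str = "median"  # dichotomic only

    def __post_init__(self) -> None:
        if self.mode not in ("dichotomic", "minmax"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size == 2 and set(u) <= {0.0, 1.0}


def dichotomize(values: np.ndarray, split: float | str = "median") -> np.ndarray:
    """Binarize a vector: 1 iff value > split (default split: the median).

    Values at or below the split map to 0, so a median split gives the most
    balanced achievable partition under ties. Already-binary {0,1} vectors
    pass through unchanged. Constant vectors raise DegenerateVariableError.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise DegenerateVariableError("constant vector cannot be dichotomized")
    if _is_binary(values):
        return values.copy()
    split_val = float(np.median(values)) if split == "median" else float(split)
    out = (values > split_val).astype(float)
    if np.unique(out).size < 2 and split == "median":
        # all mass at/below the median (heavy ties): split strictly below it
        out = (values >= split_val).astype(float)
    return out


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Affine rescale to [0,1]: min ↦ 0, max ↦ 1. Rank-preserving."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if not hi > lo:
        raise DegenerateVariableError("constant vector cannot be min-max scaled")
    return (values - lo) / (hi - lo)


def default_encodings(table: CohortTable) -> list[VariableEncoding]:
    """Median-split dichotomic encoding for every cohort variable."""
    return [VariableEncoding(name) for name, _ in table.variables]


def encode_cohort(
    table: CohortTable,
    encodings: list[VariableEncoding] | None = None,
    *,
    max_missing_fraction: float = 0.10,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the encoded subjects × variables matrix in [0,1].

    Column order follows the declaration order of ``encodings``. Variables
    with more than ``max_missing_fraction`` missing values raise; the rare
    remaining missing entries are imputed with the variable median before
    encoding. Returns (matrix, labels).
    """
    if encodings is None:
        encodings = default_encodings(table)
    if not encodings:
        raise ValueError("empty variable selection")
    names = table.variable_names
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for enc in encodings:
        if enc.source_variable not in names:
            raise KeyError(f"no such cohort variable: {enc.source_variable!r}")
        j = names.index(enc.source_variable)
        v = table.values[:, j].astype(float).copy()
        miss = table.missing_mask[:, j]
        if miss.mean() > max_missing_fraction:
            raise ValueError(
                f"{enc.source_variable}: {miss.mean():.0%} missing exceeds the "
                f"{max_missing_fraction:.0%} tolerance"
            )
        if miss.any():
            v[miss] = np.median(v[~miss])
        if enc.mode == "dichotomic":
            cols.append(dichotomize(v, enc.split_value))
        else:
            cols.append(minmax_scale(v))
        labels.append(enc.source_variable)
    return np.column_stack(cols), labels
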