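"""Matrix conditioning: valid-value filtering, downshifted imputation, width normalization.

The fixed processing order is filter -> impute -> normalize. Imputation draws
missing values from a per-sample Gaussian narrowed to ``width`` times the
sample's observed standard deviation and shifted down by ``downshift`` standard
deviations, modelling intensities missing because they fall near the detection
limit. Width normalization subtracts each sample's median and rescales to unit
interquartile range so samples are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "ImputeParams",
    "filter_valid_values",
    "impute",
    "width_normalize",
    "preprocess_report",
]


@dataclass(frozen=True)
class FilterParams:
    min_valid_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ImputeParams:
    width: float = 0.3
    downshift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.downshift < 0:
            raise ValueError("downshift must be non-negative")


def valid_value_threshold(n_samples: int, min_valid_fraction: float) -> int:
    """Integer retention threshold: ceil(fraction * n_samples)."""
    return math.ceil(min_valid_fraction * n_samples)


def filter_valid_values(matrix: pd.DataFrame, params: FilterParams = FilterParams()):
    """Keep proteins observed in at least ceil(fraction * n_samples) samples.

    Returns (filtered_matrix, threshold_used).
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no samples")
    thr = valid_value_threshold(matrix.shape[1], params.min_valid_fraction)
    keep = matrix.notna().sum(axis=1) >= thr
    return matrix.loc[keep], thr


def impute(matrix: pd.DataFrame, params: ImputeParams = ImputeParams()) -> pd.DataFrame:
    """Replace missing cells by draws from a downshifted per-sample normal.

    For sample j with observed mean m_j and sd s_j (ddof=1) each missing cell
    is drawn independently from Normal(m_j - downshift*s_j, (width*s_j)^2).
    Observed cells are untouched; deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        obs = vals.dropna()
        miss = vals.index[vals.isna()]
        if len(miss) == 0:
            continue
        if len(obs) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values; cannot impute")
        m, s = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(m - params.downshift * s, params.width * s, size=len(miss))
        out.loc[miss, col] = draws
    return out


def width_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per sample: subtract the median, divide by the interquartile range.

    Quantiles use linear interpolation; IQR = Q3 - Q1. Every output sample has
    median 0 and IQR 1.
    """
    if matrix.isna().any().any():
        raise ValueError("width_normalize requires a complete matrix (impute first)")
    med = matrix.median(axis=0)
    q1 = matrix.quantile(0.25, axis=0, interpolation="linear")
    q3 = matrix.quantile(0.75, axis=0, interpolation="linear")
    iqr = q3 - q1
    zero = iqr.index[iqr == 0]
    if len(zero):
        raise ValueError(f"zero interquartile range in sample(s) {list(zero)}")
    return (matrix - med) / iqr


def preprocess_report(raw: pd.DataFrame, filtered: pd.DataFrame, threshold: int) -> dict:
    """JSON-serializable summary of a preprocessing run."""
    obs = {
        c: {
            "mean": float(filtered[c].mean()),
            "sd": float(filtered[c].std(ddof=1)),
            "median": float(filtered[c].median()),
            "n_missing": int(filtered[c].isna().sum()),
        }
        for c in filtered.columns
    }
    return {
        "threshold_valid_values": threshold,
        "n_proteins_in": int(raw.shape[0]),
        "n_proteins_retained": int(filtered.shape[0]),
        "n_imputed_cells": int(filtered.isna().sum().sum()),
        "per_sample": obs,
    }
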