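"""Hybrid SILAC / label-free protein quantification.

Each peptide feature in a sample has a light intensity (the sample itself) and,
when the protein is covered by the heavy spike-in standard, a heavy intensity.
For a peptide observed in two samples the preferred between-sample comparison
is the ratio of SILAC ratios, (L_a/H_a)/(L_b/H_b), which cancels the common
standard and peptide response; when a heavy value is missing on either side the
direct light ratio L_a/L_b is used as fallback; with a light value missing the
peptide does not contribute to that pair.

Per protein group, peptide-level log ratios are summarized per sample pair by
their median, and a relative log2 intensity profile over the samples is
reconstructed as the least-squares solution of the pairwise ratio equations
x_a - x_b = r(a, b), independently on each connected component of the sample
graph. Only relative intensities are defined; an anchor rule fixes the free
additive constant per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuantConfig",
    "peptide_pair_log_ratio",
    "protein_pairwise_ratios",
    "reconstruct_profile",
    "quantify_matrix",
    "QuantReport",
]

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class QuantConfig:
    """Settings of the hybrid quantification.

    min_ratio_count: minimum number of peptide ratios supporting a sample pair.
    mode: "hybrid" uses the light-ratio fallback, "silac_only" does not.
    anchor_rule: how the free constant of each profile is fixed —
        "sum_of_light": total linear intensity matches total observed light
        intensity; "geometric_mean_one": mean log2 intensity is 0.
    """

    min_ratio_count: int = 1
    mode: str = "hybrid"
    anchor_rule: str = "sum_of_light"

    def __post_init__(self) -> None:
        if self.min_ratio_count < 1:
            raise ValueError("min_ratio_count must be >= 1")
        if self.mode not in ("hybrid", "silac_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.anchor_rule not in ("sum_of_light", "geometric_mean_one"):
            raise ValueError(f"unknown anchor_rule {self.anchor_rule!r}")


def peptide_pair_log_ratio(
    light_a, heavy_a, light_b, heavy_b, allow_light_fallback: bool = True
):
    """Log2 between-sample ratio of one peptide feature, or (None, None).

    Returns (log2_ratio, source) with source "silac" (ratio of SILAC ratios)
    or "light" (direct light-intensity ratio fallback).
    """

    def ok(x):
        return x is not None and not (isinstance(x, float) and math.isnan(x))

    if ok(light_a) and ok(heavy_a) and ok(light_b) and ok(heavy_b):
        return math.log2((light_a / heavy_a) / (light_b / heavy_b)), "silac"
    if allow_light_fallback and ok(light_a) and ok(light_b):
        return math.log2(light_a / light_b), "light"
    return None, None


def protein_pairwise_ratios(
    features: pd.DataFrame, sample_ids: list[str], config: QuantConfig
) -> tuple[dict[tuple[int, int], tuple[float, int]], bool]:
    """Median peptide log2 ratio per sample pair for one protein group.

    Returns ({(a, b): (median_log2_ratio, support)}, used_light_fallback) with
    a < b indexing into ``sample_ids``; antisymmetric entries are implied.
    Pairs with support below ``config.min_ratio_count`` are dropped.
    """
    allow_light = config.mode == "hybrid"
    pos = {s: i for i, s in enumerate(sample_ids)}
    # peptide -> {sample_index: (light, heavy)}
    per_pep: dict[str, dict[int, tuple[float, float]]] = {}
    for pep, s, li, hi in zip(
        features["peptide_id"], features["sample_id"], features["intensity_l"], features["intensity_h"]
    ):
        per_pep.setdefault(pep, {})[pos[s]] = (li, hi)

    pools: dict[tuple[int, int], list[float]] = {}
    used_light = False
    for obs in per_pep.values():
        idx = sorted(obs)
        for i, a in enumerate(idx):
            for b in idx[i + 1 :]:
                la, ha = obs[a]
                lb, hb = obs[b]
                r, src = peptide_pair_log_ratio(la, ha, lb, hb, allow_light)
                if r is None:
                    continue
                if src == "light":
                    used_light = True
                pools.setdefault((a, b), []).append(r)

    out = {
        pair: (float(np.median(vals)), len(vals))
        for pair, vals in pools.items()
        if len(vals) >= config.min_ratio_count
    }
    return out, used_light


def _components(n: int, edges) -> list[list[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [g for g in groups.values() if len(g) >= 1]


def reconstruct_profile(
    ratios: dict[tuple[int, int], tuple[float, int]],
    n_samples: int,
    config: QuantConfig = QuantConfig(),
    light_totals: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares log2 profile from pairwise log ratios.

    Minimizes sum over defined pairs of (x_a - x_b - r(a,b))^2 within each
    connected component of the sample graph; samples in no component are NaN.
    The free constant per component is fixed by ``config.anchor_rule``
    ("sum_of_light" requires ``light_totals``, the per-sample summed observed
    light intensity; it falls back to geometric_mean_one when unavailable).
    """
    x = np.full(n_samples, np.nan)
    if not ratios:
        return x
    edges = list(ratios)
    for comp in _components(n_samples, edges):
        comp_edges = [(a, b) for a, b in edges if a in comp and b in comp]
        if not comp_edges and len(comp) == 1:
            continue  # isolated sample: no ratio information
        loc = {s: i for i, s in enumerate(comp)}
        m, k = len(comp_edges), len(comp)
        A = np.zeros((m + 1, k))
        y = np.zeros(m + 1)
        for row, (a, b) in enumerate(comp_edges):
            A[row, loc[a]] = 1.0
            A[row, loc[b]] = -1.0
            y[row] = ratios[(a, b)][0]
        A[m, :] = 1.0  # gauge row: pin the mean to 0, removes the null space
        sol = np.linalg.lstsq(A, y, rcond=None)[0]
        if config.anchor_rule == "sum_of_light" and light_totals is not None:
            total = float(np.nansum(light_totals[comp]))
            if total > 0:
                sol += math.log2(total) - math.log2(np.sum(2.0**sol))
        for s, i in loc.items():
            x[s] = sol[i]
    return x


@dataclass
class QuantReport:
    """Bookkeeping of one quantification run."""

    mode: str
    n_protein_groups: int = 0
    n_quantified: int = 0
    n_with_light_fallback: int = 0
    fallback_proteins: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_protein_groups": self.n_protein_groups,
            "n_quantified": self.n_quantified,
            "n_with_light_fallback": self.n_with_light_fallback,
        }


def _validate_table(table: pd.DataFrame) -> None:
    for col in ("protein_group_id", "peptide_id", "sample_id", "intensity_l", "intensity_h"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    for col in ("intensity_l", "intensity_h"):
        bad = table.index[table[col].notna() & (table[col] <= 0)]
        if len(bad):
            raise ValueError(f"non-positive {col} at rows {list(bad[:5])}")
    dup = table.duplicated(subset=["peptide_id", "sample_id"])
    if dup.any():
        raise ValueError(f"duplicated (peptide, sample) rows at {list(table.index[dup][:5])}")
    multi = table.groupby("peptide_id")["protein_group_id"].nunique()
    shared = multi.index[multi > 1]
    if len(shared):
        raise ValueError(f"peptides mapped to multiple protein groups: {list(shared[:5])}")


def quantify_matrix(
    table: pd.DataFrame, config: QuantConfig = QuantConfig()
) -> tuple[pd.DataFrame, QuantReport]:
    """Protein x sample matrix of log2 relative intensities.

    Applies the pairwise-ratio and least-squares steps per protein group.
    Returns (matrix, report); matrix entries are NaN where unquantified. The
    report records which proteins used the light-intensity fallback.
    """
    _validate_table(table)
    sample_ids = sorted(table["sample_id"].unique())
    report = QuantReport(mode=config.mode)
    profiles: dict[str, np.ndarray] = {}
    for pg, grp in table.groupby("protein_group_id", sort=True):
        report.n_protein_groups += 1
        ratios, used_light = protein_pairwise_ratios(grp, sample_ids, config)
        totals = (
            grp.groupby("sample_id")["intensity_l"].sum(min_count=1).reindex(sample_ids).to_numpy()
        )
        prof = reconstruct_profile(ratios, len(sample_ids), config, light_totals=totals)
        if np.isfinite(prof).any():
            report.n_quantified += 1
            if used_light:
                report.n_with_light_fallback += 1
                report.fallback_proteins.append(pg)
        profiles[pg] = prof
    matrix = pd.DataFrame.from_dict(profiles, orient="index", columns=sample_ids)
    matrix = matrix.sort_index()
    matrix.index.name = "protein_group_id"
    return matrix, report
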