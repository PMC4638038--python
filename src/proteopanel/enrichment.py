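"""Category enrichment: Fisher tests with BH correction and 1D/2D rank scores.

Two flavours of enrichment are provided. Component-driver enrichment asks
whether an annotation category is over-represented among the proteins with the
largest loadings on a principal component (two-sided Fisher exact test per
category, Benjamini-Hochberg correction across categories). Rank-based
enrichment scores summarize where a category's proteins sit in a ranked value
vector: the Mann-Whitney rank-sum statistic is rescaled to [-1, 1], so a score
near 1 means the category occupies the top ranks and near -1 the bottom ranks.
The 2D variant scores a category in two value dimensions at once (e.g. the
median profiles of two tumor subtypes) to expose categories that behave
differently between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .unsupervised import PCAResult

__all__ = [
    "fisher_exact",
    "bh_adjust",
    "component_driver_enrichment",
    "enrichment_score_1d",
    "enrichment_2d",
]

SIGNIFICANCE_CUTOFF = 0.05


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by summation of hypergeometric tables with probability at most
    that of the observed table (the classical definition).
    """
    tbl = np.asarray(table, dtype=int)
    if tbl.shape != (2, 2) or (tbl < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    return float(stats.fisher_exact(tbl, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score_1d(values: pd.Series, members: set[str]) -> tuple[float, float]:
    """Rank-based enrichment score in [-1, 1] plus two-sided Mann-Whitney p.

    With U the rank-sum statistic of the member group (mid-ranks for ties),
    the score is 2*U/(m*(n-m)) - 1: +1 iff members occupy all top ranks, -1
    iff all bottom ranks, expectation 0 under exchangeability.
    """
    ids = values.index
    member_mask = ids.isin(members)
    m = int(member_mask.sum())
    n = len(values)
    if m == 0 or m == n:
        raise ValueError("member set must be a proper non-empty subset of the IDs")
    ranks = stats.rankdata(values.to_numpy())
    u = float(ranks[member_mask].sum() - m * (m + 1) / 2.0)
    score = 2.0 * u / (m * (n - m)) - 1.0
    x = values.to_numpy()[member_mask]
    y = values.to_numpy()[~member_mask]
    has_ties = len(np.unique(values.to_numpy())) < n
    method = "exact" if (max(m, n - m) <= 25 and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return score, p


@dataclass
class EnrichmentRow:
    category: str
    p_value: float
    q_value: float = np.nan
    enrichment_factor: float = np.nan
    score_x: float = np.nan
    score_y: float = np.nan
    n_members: int = 0
    significant: bool = False


def component_driver_enrichment(
    pca_result: PCAResult,
    component: str,
    catalog: dict[str, set[str]],
    loading_quantile: float = 0.9,
) -> tuple[pd.DataFrame, int]:
    """Fisher enrichment of categories among a component's top-loading proteins.

    A protein is "associated" with the component when its |loading| exceeds the
    ``loading_quantile`` quantile of all |loadings| on that component. Per
    category the 2x2 table (associated x in-category) feeds a two-sided Fisher
    test; BH correction is applied across categories. The enrichment factor is
    the in-category fraction among associated proteins divided by the overall
    in-category fraction. Categories with no protein in the matrix are skipped
    (returned as a warning count).
    """
    load = pca_result.loadings[component].abs()
    cutoff = float(np.quantile(load.to_numpy(), loading_quantile))
    associated = set(load.index[load > cutoff])
    if not associated:
        raise ValueError("degenerate loadings: no protein exceeds the quantile cutoff")
    universe = set(load.index)
    n = len(universe)
    rows, skipped = [], 0
    for cat, ids in catalog.items():
        members = ids & universe
        if not members:
            skipped += 1
            continue
        a = len(associated & members)
        b = len(associated) - a
        c = len(members) - a
        d = n - a - b - c
        p = fisher_exact([[a, b], [c, d]])
        expected = len(members) / n
        observed = a / len(associated)
        rows.append(
            EnrichmentRow(
                category=cat,
                p_value=p,
                enrichment_factor=observed / expected if expected > 0 else np.nan,
                n_members=len(members),
            )
        )
    if rows:
        q = bh_adjust([r.p_value for r in rows])
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
            r.significant = bool(qv <= SIGNIFICANCE_CUTOFF)
    df = pd.DataFrame([vars(r) for r in rows]).drop(columns=["score_x", "score_y"], errors="ignore")
    return df, skipped


def enrichment_2d(
    dim_x: pd.Series,
    dim_y: pd.Series,
    catalog: dict[str, set[str]],
    fdr: float = SIGNIFICANCE_CUTOFF,
) -> pd.DataFrame:
    """Two-dimensional rank enrichment of categories.

    Scores each category in both dimensions with ``enrichment_score_1d``. The
    joint p-value is the smaller of the two per-dimension Mann-Whitney p values
    with a Bonferroni factor of 2 (conservative combination); BH correction
    across categories with significance at ``fdr``.
    """
    shared = dim_x.index.intersection(dim_y.index)
    x = dim_x.loc[shared]
    y = dim_y.loc[shared]
    rows = []
    for cat, ids in catalog.items():
        members = ids & set(shared)
        if not members or len(members) == len(shared):
            continue
        sx, px = enrichment_score_1d(x, members)
        sy, py = enrichment_score_1d(y, members)
        joint = min(1.0, 2.0 * min(px, py))
        rows.append(
            EnrichmentRow(
                category=cat, p_value=joint, score_x=sx, score_y=sy, n_members=len(members)
            )
        )
    if rows:
        q = bh_adjust([r.p_value for r in rows])
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
            r.significant = bool(qv <= fdr)
    return pd.DataFrame([vars(r) for r in rows]).drop(columns=["enrichment_factor"], errors="ignore")


# ---------------------------------------------------------------------------
# Catalog I/O: two-column TSV (category<TAB>protein_id) or GMT


def read_catalog(path) -> dict[str, set[str]]:
    catalog: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        gmt = len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            if parts[:2] == ["category", "protein_id"]:
                continue  # header of the two-column dialect
            if gmt:
                catalog.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
            else:
                catalog.setdefault(parts[0], set()).add(parts[1])
    return catalog


def write_catalog(catalog: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tprotein_id\n")
        for cat in sorted(catalog):
            for pid in sorted(catalog[cat]):
                fh.write(f"{cat}\t{pid}\n")
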