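"""Synthetic peptide-level cohort generator.

Emulates a two-subtype tumor cohort measured by super-SILAC mass spectrometry:
each sample carries a light (sample-specific) channel and a heavy channel from a
common spike-in standard mixed 1:1. The standard covers only a fraction of the
proteome — proteins absent from it (e.g. secreted / extracellular-matrix-like
proteins in real cohorts) have no heavy intensities anywhere. Detection is
missing-not-at-random: the probability of observing a peptide intensity rises
logistically with its log10 intensity, mimicking the instrument detection limit.

The generator starts at the peptide-feature intensity level that the
quantification algorithm consumes; it does not simulate chromatography, charge
states or spectral identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CohortTruth",
    "generate_cohort",
    "generate_annotations",
    "write_feature_table",
    "read_feature_table",
    "write_truth",
    "write_labels",
    "read_labels",
]

#: Mean log10 base abundance of a protein (typical MS intensity scale ~1e7).
BASE_LOG10_MEAN = 7.0
#: Spread (log10) of peptide-specific response factors (ionization efficiency).
RESPONSE_SD_LOG10 = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design this generator emulates: 13 + 7 samples of
    two molecular subtypes, protein abundances spanning several orders of
    magnitude, a heavy standard covering ~80% of proteins, and a small planted
    set of subtype-differential proteins.
    """

    n_samples_A: int = 13
    n_samples_B: int = 7
    n_proteins: int = 1000
    frac_differential: float = 0.05
    log2fc_range: tuple[float, float] = (1.0, 2.0)
    frac_in_standard: float = 0.8
    peptides_per_protein_mean: float = 4.0
    abundance_sd_log10: float = 1.0
    noise_cv: float = 0.1
    detection_midpoint: float = 6.0
    detection_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_A < 1 or self.n_samples_B < 1 or self.n_proteins < 1:
            raise ValueError("sample and protein counts must be >= 1")
        for name in ("frac_differential", "frac_in_standard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.log2fc_range
        if not (lo > 0 and hi > 0 and lo <= hi):
            raise ValueError("log2fc_range must be positive with lo <= hi")
        if self.peptides_per_protein_mean < 1:
            raise ValueError("peptides_per_protein_mean must be >= 1")
        if self.abundance_sd_log10 <= 0:
            raise ValueError("abundance_sd_log10 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.detection_slope < 0:
            raise ValueError("detection_slope must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    true_log2_abundance: pd.DataFrame  # proteins x samples
    differential_ids: set[str]
    log2fc: dict[str, float]  # signed; 0.0 for non-differential
    in_standard: dict[str, bool]
    subtype_labels: pd.Series  # sample -> "A" | "B"
    protein_ids: list[str] = field(default_factory=list)

    @property
    def standard_absent_ids(self) -> set[str]:
        return {p for p, s in self.in_standard.items() if not s}


def _detection_prob(log10_intensity: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.detection_slope == 0:
        return np.ones_like(log10_intensity)
    z = (log10_intensity - cfg.detection_midpoint) * cfg.detection_slope
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a peptide feature table and its ground truth.

    Deterministic given ``config.seed``. A single RNG stream is consumed in a
    fixed documented order (protein-level draws, then per-protein peptide
    draws, then per-peptide sample-level draws), so changing any count changes
    later draws.

    Returns
    -------
    table : DataFrame with columns
        protein_group_id, peptide_id, sample_id, intensity_l, intensity_h
        (NaN = missing; intensities strictly positive when present).
    truth : CohortTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    sample_ids = [f"S_A{i:02d}" for i in range(cfg.n_samples_A)] + [
        f"S_B{i:02d}" for i in range(cfg.n_samples_B)
    ]
    labels = pd.Series(
        ["A"] * cfg.n_samples_A + ["B"] * cfg.n_samples_B,
        index=sample_ids,
        name="subtype",
    )
    n_samples = len(sample_ids)
    is_b = (labels == "B").to_numpy()

    # --- protein-level draws ---
    base_log10 = rng.normal(BASE_LOG10_MEAN, cfg.abundance_sd_log10, size=n)
    n_diff = int(round(cfg.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    fc_mag = rng.uniform(cfg.log2fc_range[0], cfg.log2fc_range[1], size=n_diff)
    fc_sign = rng.choice([-1.0, 1.0], size=n_diff)
    log2fc = np.zeros(n)
    log2fc[diff_idx] = fc_mag * fc_sign
    n_std = int(round(cfg.frac_in_standard * n))
    std_idx = rng.choice(n, size=n_std, replace=False)
    in_standard = np.zeros(n, dtype=bool)
    in_standard[std_idx] = True

    # true light-channel log2 abundance: base plus subtype-B fold change
    base_log2 = base_log10 / math.log10(2.0)
    true_log2 = np.tile(base_log2[:, None], (1, n_samples))
    true_log2[:, is_b] += log2fc[:, None]

    noise_sd_ln = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0

    rows_pg, rows_pep, rows_s, rows_l, rows_h = [], [], [], [], []
    log10_2 = math.log10(2.0)
    for i in range(n):
        n_pep = 1 + rng.poisson(cfg.peptides_per_protein_mean - 1.0)
        resp_log10 = rng.normal(0.0, RESPONSE_SD_LOG10, size=n_pep)
        for p in range(n_pep):
            pep_id = f"{protein_ids[i]}_pep{p}"
            light_log10 = true_log2[i] * log10_2 + resp_log10[p]
            heavy_log10 = base_log10[i] + resp_log10[p]
            if noise_sd_ln > 0:
                light_log10 = light_log10 + rng.normal(0, noise_sd_ln, n_samples) / math.log(10)
                heavy_log10 = heavy_log10 + rng.normal(0, noise_sd_ln, n_samples) / math.log(10)
            # a peptide feature is the co-eluting light/heavy isotope pair:
            # it is detected (or not) as a unit, with probability driven by
            # the light (sample) log-intensity
            det = rng.random(n_samples) < _detection_prob(light_log10, cfg)
            light = np.where(det, 10.0**light_log10, np.nan)
            heavy = (
                np.where(det, 10.0**heavy_log10, np.nan)
                if in_standard[i]
                else np.full(n_samples, np.nan)
            )
            if not det.any():
                continue
            idx = np.nonzero(det)[0]
            rows_pg.extend([protein_ids[i]] * len(idx))
            rows_pep.extend([pep_id] * len(idx))
            rows_s.extend(sample_ids[j] for j in idx)
            rows_l.extend(light[idx])
            rows_h.extend(heavy[idx])

    table = pd.DataFrame(
        {
            "protein_group_id": rows_pg,
            "peptide_id": rows_pep,
            "sample_id": rows_s,
            "intensity_l": rows_l,
            "intensity_h": rows_h,
        }
    )
    truth = CohortTruth(
        true_log2_abundance=pd.DataFrame(true_log2, index=protein_ids, columns=sample_ids),
        differential_ids={protein_ids[i] for i in diff_idx},
        log2fc={protein_ids[i]: float(log2fc[i]) for i in range(n)},
        in_standard={protein_ids[i]: bool(in_standard[i]) for i in range(n)},
        subtype_labels=labels,
        protein_ids=protein_ids,
    )
    return table, truth


def generate_annotations(
    truth: CohortTruth,
    n_categories: int,
    category_size: int,
    frac_differential_category: float,
    seed: int,
    include_extracellular_like: bool = True,
) -> dict[str, set[str]]:
    """Random annotation catalog plus one planted positive-control category.

    The planted category draws each member from the differential set with
    probability ``frac_differential_category`` (uniformly from the rest
    otherwise), giving enrichment tests a known signal. When the cohort has
    standard-absent proteins, an ``extracellular_like`` category collecting
    them is added, mimicking secreted/ECM proteins that a cell-line standard
    misses.
    """
    ids = list(truth.protein_ids)
    if category_size > len(ids):
        raise ValueError("category_size exceeds number of proteins")
    if not 0.0 <= frac_differential_category <= 1.0:
        raise ValueError("frac_differential_category must be in [0, 1]")
    rng = np.random.default_rng(seed)
    catalog: dict[str, set[str]] = {}
    for c in range(n_categories):
        pick = rng.choice(len(ids), size=category_size, replace=False)
        catalog[f"random_{c:03d}"] = {ids[j] for j in pick}

    diff = sorted(truth.differential_ids)
    non_diff = sorted(set(ids) - truth.differential_ids)
    planted: set[str] = set()
    while len(planted) < category_size:
        from_diff = diff and rng.random() < frac_differential_category
        pool = diff if from_diff else non_diff
        if not pool:
            pool = ids
        cand = pool[rng.integers(len(pool))]
        planted.add(cand)
    catalog["planted"] = planted

    if include_extracellular_like:
        absent = truth.standard_absent_ids
        if absent:
            catalog["extracellular_like"] = set(absent)
    return catalog


# ---------------------------------------------------------------------------
# TSV serialization (empty field = missing)

FEATURE_COLUMNS = ["protein_group_id", "peptide_id", "sample_id", "intensity_l", "intensity_h"]


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6f")


def read_feature_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a peptide feature table TSV.

    ``column_map`` renames input columns to the canonical header (e.g.
    ``{"Protein group IDs": "protein_group_id", ...}``), so evidence-style
    exports from search-engine software can be adapted.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    for c in FEATURE_COLUMNS[:3]:
        if c in df.columns:
            df[c] = df[c].astype(str)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    for c in ("intensity_l", "intensity_h"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_truth(truth: CohortTruth, prefix) -> None:
    """Write ground-truth sidecar files: <prefix>.abundance.tsv, <prefix>.proteins.tsv."""
    truth.true_log2_abundance.to_csv(f"{prefix}.abundance.tsv", sep="\t")
    meta = pd.DataFrame(
        {
            "protein_group_id": truth.protein_ids,
            "differential": [p in truth.differential_ids for p in truth.protein_ids],
            "log2fc": [truth.log2fc[p] for p in truth.protein_ids],
            "in_standard": [truth.in_standard[p] for p in truth.protein_ids],
        }
    )
    meta.to_csv(f"{prefix}.proteins.tsv", sep="\t", index=False)


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="subtype")
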