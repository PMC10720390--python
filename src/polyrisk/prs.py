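"""Polygenic risk score: weighted-sum scoring, polymorphic-variant filtering
and control-anchored tertile categories.

The score is the raw weighted sum s_i = sum_j w_j g_ij of effect-allele
dosages g_ij in [0, 2] (not standardized; a ``standardize`` flag exists for
convenience). Scoring-file variants are first restricted to those polymorphic
in the study's controls (MAF > 1%). Tertile cut points are the 1/3 and 2/3
quantiles (type-7 linear interpolation) of the CONTROL score distribution;
every individual, cases included, is then categorized by those cut points
with left-closed upper bands: low < q1 <= intermediate < q2 <= high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_cohort import logger

MAF_POLYMORPHIC = 0.01
MAX_MISSING_FRACTION = 0.10


@dataclass
class PRSModel:
    """Scoring model: per-variant effect/other alleles and weights."""

    entries: pd.DataFrame  # columns: variant_id, effect_allele, other_allele, weight

    def __post_init__(self):
        ids = self.entries["variant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant ids in PRS model")
        if not np.isfinite(self.entries["weight"]).all():
            raise ValueError("non-finite PRS weight")

    @classmethod
    def from_scoring(cls, scoring: pd.DataFrame) -> "PRSModel":
        return cls(scoring[["variant_id", "effect_allele", "other_allele", "weight"]].copy())

    @property
    def variant_ids(self) -> list:
        return list(self.entries["variant_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(dtype=float)


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    dropped_low_maf: list = field(default_factory=list)
    dropped_absent: list = field(default_factory=list)


def control_allele_frequencies(dosages: pd.DataFrame, control_ids) -> pd.Series:
    """Effect-allele frequency in controls, per variant (mean dosage / 2)."""
    ctrl = dosages.loc[dosages.index.intersection(pd.Index(control_ids))]
    if len(ctrl) == 0:
        raise ValueError("no controls present in dosage table")
    return ctrl.mean(axis=0, skipna=True) / 2.0


def filter_polymorphic(model: PRSModel, dosages: pd.DataFrame, control_ids) -> tuple[PRSModel, FilterReport]:
    """Retain model variants polymorphic in controls (MAF > 1%) and present
    in the dosage table; report dropped ids."""
    af = control_allele_frequencies(dosages, control_ids)
    keep, low, absent = [], [], []
    for vid in model.entries["variant_id"]:
        if vid not in af.index or pd.isna(af[vid]):
            absent.append(vid)
            continue
        maf = min(af[vid], 1.0 - af[vid])
        if maf > MAF_POLYMORPHIC:
            keep.append(vid)
        else:
            low.append(vid)
    report = FilterReport(len(model.entries), len(keep), low, absent)
    if low or absent:
        logger.info(
            "filter_polymorphic: retained %d/%d (dropped %d low-MAF, %d absent)",
            report.n_retained, report.n_input, len(low), len(absent),
        )
    filtered = model.entries[model.entries["variant_id"].isin(keep)].reset_index(drop=True)
    return PRSModel(filtered), report


def compute_scores(
    model: PRSModel,
    dosages: pd.DataFrame,
    control_ids=None,
    standardize: bool = False,
) -> pd.Series:
    """Weighted-sum PRS per individual.

    A missing single dosage is imputed as twice the effect-allele frequency in
    controls (the mean dosage under Hardy-Weinberg); individuals missing more
    than 10% of model variants get a missing (NaN) score and are reported.
    """
    missing_cols = [v for v in model.variant_ids if v not in dosages.columns]
    if missing_cols:
        raise ValueError(f"dosage table lacks model variants: {missing_cols[:5]}")
    g = dosages[model.variant_ids].to_numpy(dtype=float)
    miss = np.isnan(g)
    too_missing = miss.mean(axis=1) > MAX_MISSING_FRACTION if g.shape[1] else np.zeros(len(g), bool)
    if miss.any():
        af = control_allele_frequencies(dosages, control_ids if control_ids is not None else dosages.index)
        fill = 2.0 * af.reindex(model.variant_ids).to_numpy(dtype=float)
        fill = np.where(np.isnan(fill), 0.0, fill)
        g = np.where(miss, fill[None, :], g)
    s = g @ model.weights
    s[too_missing] = np.nan
    if too_missing.any():
        logger.warning("compute_scores: %d individuals exceed %.0f%% missing dosages; score set missing",
                       int(too_missing.sum()), MAX_MISSING_FRACTION * 100)
    if standardize:
        s = (s - np.nanmean(s)) / np.nanstd(s)
    return pd.Series(s, index=dosages.index, name="score")


def tertile_cutpoints(control_scores: np.ndarray) -> tuple[float, float]:
    """Control-distribution 1/3 and 2/3 quantiles (type-7 interpolation)."""
    cs = np.asarray(control_scores, dtype=float)
    cs = cs[~np.isnan(cs)]
    if len(cs) < 3:
        raise ValueError("need at least 3 control scores for tertiles")
    if np.ptp(cs) == 0:
        raise ValueError("degenerate control distribution: all control scores identical")
    q1, q2 = np.quantile(cs, [1.0 / 3.0, 2.0 / 3.0])
    return float(q1), float(q2)


def assign_categories(scores: pd.Series, control_ids) -> pd.DataFrame:
    """Assign low/intermediate/high by control-derived tertile cut points.

    Returns a DataFrame (index individual_id) with columns ``score`` and
    ``category``. Band rule: low < q1 <= intermediate < q2 <= high.
    """
    ctrl = scores.loc[scores.index.intersection(pd.Index(control_ids))]
    q1, q2 = tertile_cutpoints(ctrl.to_numpy())
    cat = pd.Series("intermediate", index=scores.index, dtype=object)
    cat[scores < q1] = "low"
    cat[scores >= q2] = "high"
    cat[scores.isna()] = pd.NA
    return pd.DataFrame({"score": scores, "category": cat})


def score_and_categorize(
    scoring: pd.DataFrame,
    dosages: pd.DataFrame,
    control_ids,
    standardize: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full PRS stage: polymorphic filter -> weighted sum -> control tertiles."""
    model, report = filter_polymorphic(PRSModel.from_scoring(scoring), dosages, control_ids)
    scores = compute_scores(model, dosages, control_ids, standardize=standardize)
    return assign_categories(scores, control_ids), report
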