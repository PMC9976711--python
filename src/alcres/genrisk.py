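"""Genetic-risk indices: family history density, PRS standardization, and
the high-genetic-risk subsetting rule.

Family history density aggregates log-transformed maximum AUD symptom
counts over first- and second-degree relatives, weighted by degree of
relatedness (w = 0.5 for first degree, 0.25 for second).  The default form
divides by the total weight of assessed relatives (a weighted mean); a raw
weighted sum is selectable.  The polygenic score is standardized within
ancestry group before pooling, and a subject is high-risk if family
history density is non-zero or the standardized PRS falls in the sample's
top quartile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from alcres.synthdata import RelativeRecord

__all__ = [
    "GeneticRisk",
    "family_history_density",
    "top_quartile_flag",
    "standardize_prs",
    "compute_genetic_risk",
]

DEGREE_WEIGHTS = {1: 0.5, 2: 0.25}


@dataclass
class GeneticRisk:
    subject_id: str
    fhd: float
    prs_z: float
    high_risk: bool


def family_history_density(
    relatives: Iterable[RelativeRecord],
    *,
    form: str = "weighted_mean",
    log_base: str = "natural",
) -> float:
    """Relatedness-weighted aggregate of log(1 + max symptom count).

    ``form='weighted_mean'`` divides the weighted sum by the total weight
    of assessed relatives; ``'weighted_sum'`` returns the raw sum.  With no
    relatives the density is 0 under either form.
    """
    if form not in ("weighted_mean", "weighted_sum"):
        raise ValueError(f"unknown fhd form {form!r}")
    log = math.log if log_base == "natural" else math.log10
    if log_base not in ("natural", "log10"):
        raise ValueError(f"unknown log base {log_base!r}")
    num = 0.0
    denom = 0.0
    count = 0
    for rel in relatives:
        if rel.degree not in DEGREE_WEIGHTS:
            raise ValueError(f"unknown degree of relatedness {rel.degree!r}")
        if rel.aud_max_symptoms < 0:
            raise ValueError("symptom counts must be non-negative")
        w = DEGREE_WEIGHTS[rel.degree]
        num += w * log(1 + rel.aud_max_symptoms)
        denom += w
        count += 1
    if count == 0:
        return 0.0
    return num / denom if form == "weighted_mean" else num


def top_quartile_flag(prs_values: Sequence[float]) -> np.ndarray:
    """Boolean flag per value: at or above the sample 75th percentile.

    The percentile is computed over non-missing values with linear
    interpolation; ties at the cut are included; missing values get a
    missing flag (returned as NaN in a float array).
    """
    arr = np.asarray(prs_values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError("all PRS values are missing")
    if obs.size < 4:
        raise ValueError("need at least 4 non-missing PRS values for a quartile cut")
    cut = np.percentile(obs, 75.0)
    out = np.where(np.isnan(arr), np.nan, (arr >= cut).astype(float))
    return out


def standardize_prs(prs: Sequence[float], ancestry: Sequence[str]) -> np.ndarray:
    """Z-score the polygenic score within each ancestry group, then pool."""
    arr = np.asarray(prs, dtype=float)
    groups = np.asarray(ancestry)
    out = np.full(arr.shape, np.nan)
    for g in pd.unique(groups):
        mask = (groups == g) & ~np.isnan(arr)
        if mask.sum() < 2:
            continue
        mu, sd = arr[mask].mean(), arr[mask].std()
        out[mask] = (arr[mask] - mu) / sd if sd > 0 else 0.0
    return out


def compute_genetic_risk(
    subjects_df: pd.DataFrame,
    relatives_df: pd.DataFrame,
    *,
    fhd_form: str = "weighted_mean",
    fhd_log_base: str = "natural",
) -> pd.DataFrame:
    """Per-subject FHD, within-ancestry standardized PRS, and high-risk flag."""
    rel_by_family: dict[int, list[RelativeRecord]] = {}
    for r in relatives_df.itertuples():
        rel_by_family.setdefault(int(r.family_id), []).append(
            RelativeRecord(
                family_id=int(r.family_id),
                relative_id=str(r.relative_id),
                degree=int(r.degree),
                relation_label=str(r.relation_label),
                aud_max_symptoms=int(r.aud_max_symptoms),
            )
        )
    fhd = np.array(
        [
            family_history_density(
                rel_by_family.get(int(fam), []), form=fhd_form, log_base=fhd_log_base
            )
            for fam in subjects_df["family_id"]
        ]
    )
    prs_z = standardize_prs(subjects_df["prs"], subjects_df["ancestry_group"])
    quart = top_quartile_flag(prs_z)
    high = (fhd > 0) | (quart == 1.0)
    return pd.DataFrame(
        {
            "subject_id": subjects_df["subject_id"],
            "fhd": fhd,
            "prs_z": prs_z,
            "prs_top_quartile": quart,
            "high_risk": high,
        }
    )
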