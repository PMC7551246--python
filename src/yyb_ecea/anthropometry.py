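"""Height-for-age standardization, stunting classification and prevalence.

HAZ = (height - reference median) / reference SD for the child's sex and
age in months.  A child is stunted when HAZ is strictly below -2 SD; a
child sitting exactly at -2 is *not* stunted (the boundary rule is fixed
for reproducibility, ties being measure-zero with continuous heights).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .growth import GrowthReference

STUNTING_THRESHOLD = -2.0

#: Columns of the per-child HAZ table produced by :func:`haz_table`.
HAZ_COLUMNS = ["child_id", "haz", "stunted"]


class EmptyGroupError(ValueError):
    """Prevalence is undefined for an empty group (reported as NA upstream)."""


def compute_haz(height_cm: float, age_months: int, sex: str, ref: GrowthReference) -> float:
    """Height-for-age Z-score for a single child.

    Raises
    ------
    KeyError
        If (sex, age_months) is absent from the reference.
    ValueError
        If height is non-positive.
    """
    if height_cm <= 0:
        raise ValueError(f"height_cm must be positive, got {height_cm}")
    median, sd = ref.median_sd(sex, age_months)
    return (height_cm - median) / sd


def classify_stunting(haz: float | np.ndarray) -> bool | np.ndarray:
    """Strict threshold rule: stunted iff HAZ < -2."""
    arr = np.asarray(haz, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("HAZ values must be finite")
    out = arr < STUNTING_THRESHOLD
    return bool(out) if np.isscalar(haz) or arr.ndim == 0 else out


def haz_table(children: pd.DataFrame, ref: GrowthReference) -> pd.DataFrame:
    """Vectorized HAZ + stunting flags for a children table.

    Parameters
    ----------
    children
        DataFrame with at least ``child_id``, ``sex``, ``age_months``,
        ``height_cm`` columns (the microdata schema).

    Returns
    -------
    DataFrame with columns ``child_id``, ``haz``, ``stunted``, aligned
    row-for-row with the input.
    """
    if (children["height_cm"] <= 0).any():
        raise ValueError("all heights must be positive")
    median, sd = ref.lookup_arrays(children["sex"], children["age_months"])
    haz = (children["height_cm"].to_numpy() - median) / sd
    return pd.DataFrame(
        {
            "child_id": children["child_id"].to_numpy(),
            "haz": haz,
            "stunted": classify_stunting(haz),
        }
    )


def prevalence(stunted, weights=None) -> float:
    """(Weighted) stunting prevalence of a group.

    Parameters
    ----------
    stunted
        Boolean sequence of stunting flags (or a HAZ-table DataFrame, in
        which case its ``stunted`` column is used).
    weights
        Optional positive survey weights, same length.  Uniform weights
        reduce to the unweighted fraction; rescaling all weights by a
        constant leaves the result unchanged.

    Raises
    ------
    EmptyGroupError
        For an empty group: prevalence is undefined and is rendered as
        NA in reports.
    """
    if isinstance(stunted, pd.DataFrame):
        stunted = stunted["stunted"]
    flags = np.asarray(stunted, dtype=bool)
    if flags.size == 0:
        raise EmptyGroupError("prevalence undefined for an empty group")
    if weights is None:
        return float(flags.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != flags.shape:
        raise ValueError("weights must have the same length as the record list")
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    return float(np.dot(flags, w) / w.sum())


def prevalence_or_nan(stunted, weights=None) -> float:
    """Like :func:`prevalence` but maps an empty group to NaN (NA cell)."""
    try:
        return prevalence(stunted, weights)
    except EmptyGroupError:
        return math.nan
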