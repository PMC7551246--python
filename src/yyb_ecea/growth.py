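"""Growth reference tables for height-for-age standardization.

A growth reference maps (sex, age in months) to the reference-population
median height and standard deviation used to compute height-for-age
Z-scores (HAZ).  The bundled table is a *synthetic* simplified reference
(medians/SDs interpolated between standard anchor values, not the WHO LMS
tables); any CSV with columns ``sex,age_months,median_cm,sd_cm`` covering
ages 6-36 months for both sexes can be substituted.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

AGE_MIN = 6
AGE_MAX = 36
SEXES = ("male", "female")

_BUNDLED_NAME = "growth_reference_synthetic.csv"


class GrowthReferenceError(ValueError):
    """Raised when a growth reference table fails validation."""


class GrowthReference:
    """Lookup of (median height, SD) by sex and age in months.

    Parameters
    ----------
    table
        DataFrame with columns ``sex`` (``male``/``female``),
        ``age_months`` (int), ``median_cm`` (> 0) and ``sd_cm`` (> 0).
        Must cover every age in [6, 36] for both sexes, with medians
        non-decreasing in age within each sex.
    """

    def __init__(self, table: pd.DataFrame):
        self._validate(table)
        self._table = table.reset_index(drop=True)
        self._index = table.set_index(["sex", "age_months"])[["median_cm", "sd_cm"]]

    @staticmethod
    def _validate(table: pd.DataFrame) -> None:
        required = {"sex", "age_months", "median_cm", "sd_cm"}
        missing = required - set(table.columns)
        if missing:
            raise GrowthReferenceError(f"growth reference missing columns: {sorted(missing)}")
        if (table["sd_cm"] <= 0).any():
            raise GrowthReferenceError("growth reference has non-positive sd_cm entries")
        if (table["median_cm"] <= 0).any():
            raise GrowthReferenceError("growth reference has non-positive median_cm entries")
        dup = table.duplicated(subset=["sex", "age_months"])
        if dup.any():
            raise GrowthReferenceError("duplicate (sex, age_months) entries in growth reference")
        for sex in SEXES:
            sub = table[table["sex"] == sex].sort_values("age_months")
            ages = set(sub["age_months"].tolist())
            expected = set(range(AGE_MIN, AGE_MAX + 1))
            if not expected <= ages:
                missing_ages = sorted(expected - ages)
                raise GrowthReferenceError(
                    f"growth reference incomplete for sex={sex!r}: missing ages {missing_ages}"
                )
            medians = sub[sub["age_months"].between(AGE_MIN, AGE_MAX)]["median_cm"].to_numpy()
            if (np.diff(medians) < 0).any():
                raise GrowthReferenceError(
                    f"median_cm must be non-decreasing in age for sex={sex!r}"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "GrowthReference":
        """Load the synthetic reference table shipped with the package."""
        with resources.files("yyb_ecea.data").joinpath(_BUNDLED_NAME).open("r") as fh:
            return cls(pd.read_csv(fh))

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def median_sd(self, sex: str, age_months: int) -> tuple[float, float]:
        """Return (median_cm, sd_cm) for one (sex, age) pair."""
        try:
            row = self._index.loc[(sex, age_months)]
        except KeyError:
            raise KeyError(f"no growth reference entry for sex={sex!r}, age_months={age_months}")
        return float(row["median_cm"]), float(row["sd_cm"])

    def lookup_arrays(
        self, sex: np.ndarray | pd.Series, age_months: np.ndarray | pd.Series
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup: arrays of medians and SDs aligned with inputs."""
        keys = pd.MultiIndex.from_arrays([np.asarray(sex), np.asarray(age_months)])
        try:
            rows = self._index.loc[keys]
        except KeyError as exc:
            raise KeyError(f"growth reference lookup failed: {exc}") from exc
        return rows["median_cm"].to_numpy(), rows["sd_cm"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index=False)
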