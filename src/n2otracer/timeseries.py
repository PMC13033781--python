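"""Long-format measurement container shared by the simulator and analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .species import VARIABLE_UNITS, VOCABULARY

__all__ = ["TimeSeries", "COLUMNS"]

COLUMNS = ("vial_id", "run", "replicate", "day", "variable", "value", "unit")


@dataclass
class TimeSeries:
    """Replicate-resolved measurements over days, one value per row.

    Wraps a :class:`pandas.DataFrame` with columns
    ``vial_id, run, replicate, day, variable, value, unit``. Variables come
    from the controlled vocabulary; rows are kept sorted by
    (replicate, day, variable) so days are nondecreasing within a replicate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(self.data["variable"]) - set(VOCABULARY)
        if bad:
            raise ValueError(f"unknown variables: {sorted(bad)}")
        df = self.data.loc[:, list(COLUMNS)].copy()
        df["day"] = df["day"].astype(float)
        df["value"] = df["value"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        self.data = df.sort_values(["replicate", "day", "variable"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
    ) -> "TimeSeries":
        """Build from an iterable of (vial_id, run, replicate, day, variable, value) rows."""
        rows = [
            {
                "vial_id": r[0],
                "run": r[1],
                "replicate": r[2],
                "day": r[3],
                "variable": r[4],
                "value": r[5],
                "unit": VARIABLE_UNITS.get(r[4], ""),
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)))

    # -- accessors ---------------------------------------------------------

    @property
    def replicates(self) -> Sequence[int]:
        return sorted(self.data["replicate"].unique())

    @property
    def days(self) -> Sequence[float]:
        return sorted(self.data["day"].unique())

    @property
    def variables(self) -> Sequence[str]:
        return sorted(self.data["variable"].unique())

    def channel(self, variable: str, replicate: int | None = None) -> pd.Series:
        """Values of one variable indexed by day (one replicate, or raise if ambiguous)."""
        df = self.data[self.data["variable"] == variable]
        if df.empty:
            raise KeyError(f"variable {variable!r} not present")
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        if df.duplicated("day").any():
            raise ValueError(
                f"multiple replicates present for {variable!r}; pass replicate= or use replicate_mean"
            )
        return df.set_index("day")["value"].sort_index()

    def replicate_mean(self, variable: str) -> pd.Series:
        """Per-day mean of a variable across replicates (the fitting basis)."""
        df = self.data[self.data["variable"] == variable]
        if df.empty:
            raise KeyError(f"variable {variable!r} not present")
        return df.groupby("day")["value"].mean().sort_index()

    def window(self, start_day: float, end_day: float) -> "TimeSeries":
        mask = (self.data["day"] >= start_day) & (self.data["day"] <= end_day)
        return TimeSeries(self.data[mask].copy())

    def __len__(self) -> int:
        return len(self.data)
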