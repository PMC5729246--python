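"""Tidy dose-response data container shared by the generator and the fitters."""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["circuit_id", "hsl_nM", "replicate", "observable", "value", "mu"]
CONDITION_KEYS = ["circuit_id", "hsl_nM", "observable"]


class DoseResponseDataset:
    """Replicate steady-state measurements per circuit x HSL.

    Long format, one row per replicate and observable (``RFP`` or ``GFP``):
    ``circuit_id, hsl_nM, replicate, observable, value, mu``.  ``value`` is a
    normalised per-cell synthesis rate, ``mu`` the condition's fixed growth
    rate in min^-1.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (df["value"] < 0).any():
            raise ValueError("dataset contains negative values (truncation not applied?)")
        self.df = (
            df[REQUIRED_COLUMNS]
            .sort_values(["circuit_id", "observable", "hsl_nM", "replicate"])
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def circuits(self) -> list[str]:
        return sorted(self.df["circuit_id"].unique())

    def subset(self, circuits=None, observables=None) -> "DoseResponseDataset":
        df = self.df
        if circuits is not None:
            df = df[df["circuit_id"].isin(circuits)]
        if observables is not None:
            df = df[df["observable"].isin(observables)]
        return DoseResponseDataset(df.copy())

    def sigma_table(self) -> pd.DataFrame:
        """Replicate standard deviation per condition (ddof=1; 0 for n=1)."""
        g = self.df.groupby(CONDITION_KEYS)["value"]
        out = g.std(ddof=1).fillna(0.0).rename("sigma").reset_index()
        return out

    def condition_means(self) -> pd.DataFrame:
        g = self.df.groupby(CONDITION_KEYS)
        out = g.agg(value=("value", "mean"), mu=("mu", "mean")).reset_index()
        return out

    def mu_table(self) -> pd.DataFrame:
        g = self.df.groupby(["circuit_id", "hsl_nM"])["mu"].mean().rename("mu")
        return g.reset_index()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        return cls(pd.read_csv(path))

    def with_values(self, values: np.ndarray) -> "DoseResponseDataset":
        """Copy with the value column replaced (used by the bootstrap)."""
        df = self.df.copy()
        df["value"] = np.asarray(values, dtype=float)
        return DoseResponseDataset(df)
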