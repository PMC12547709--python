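"""Covariate encoding: z-scored continuous, reference-dropped one-hot.

The encoder is always fitted on training folds only, so test subjects
never leak into the location/scale estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ttegast.schema import BINARY, CATEGORICAL, CONTINUOUS


@dataclass
class CovariateEncoder:
    schema: list
    columns: list = field(default_factory=list)
    loc: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)
    feature_names: list = field(default_factory=list)

    def fit(self, df: pd.DataFrame) -> "CovariateEncoder":
        self.columns = [s.name for s in self.schema if s.name in df.columns]
        self.feature_names = []
        for spec in self.schema:
            if spec.name not in df.columns:
                continue
            if spec.kind == CONTINUOUS:
                col = pd.to_numeric(df[spec.name], errors="raise").to_numpy(dtype=float)
                if np.isnan(col).any():
                    raise ValueError(f"missing values in {spec.name!r}: impute before encoding")
                self.loc[spec.name] = float(col.mean())
                sd = float(col.std(ddof=0))
                self.scale[spec.name] = sd if sd > 0 else 1.0
                self.feature_names.append(spec.name)
            else:
                for level in spec.levels[1:]:
                    self.feature_names.append(f"{spec.name}={level}")
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for spec in self.schema:
            if spec.name not in self.columns:
                continue
            if spec.kind == CONTINUOUS:
                col = pd.to_numeric(df[spec.name], errors="raise").to_numpy(dtype=float)
                if np.isnan(col).any():
                    raise ValueError(f"missing values in {spec.name!r}: impute before encoding")
                cols.append((col - self.loc[spec.name]) / self.scale[spec.name])
            else:
                vals = df[spec.name].to_numpy()
                unknown = set(vals) - set(spec.levels)
                if unknown:
                    raise ValueError(f"unknown level(s) {sorted(unknown)} for {spec.name!r}")
                for level in spec.levels[1:]:
                    cols.append((vals == level).astype(float))
        return np.column_stack(cols) if cols else np.zeros((len(df), 0))

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)
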