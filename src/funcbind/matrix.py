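"""In-memory container for an expression study.

`ExpressionMatrix` bundles the log2 intensity matrix (rows = probes or
genes, columns = arrays), the matching per-cell detection p-values, and the
array metadata (batch, condition, replicate). A *knockdown experiment* is
identified by the pair (condition, batch): each knockdown was transfected in
one batch, and the deliberately repeated knockdowns appear as two
experiments with the same condition in different batches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
import pandas as pd

CONTROL = "CONTROL"


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame          # rows x arrays, log2 intensities
    detection_p: pd.DataFrame     # same shape as values
    arrays: pd.DataFrame          # index array_id; columns batch, condition, replicate

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.detection_p.columns) or not (
            self.values.index.equals(self.detection_p.index)
        ):
            raise ValueError("values and detection_p must share shape and labels")
        missing = set(self.values.columns) - set(self.arrays.index)
        if missing:
            raise ValueError(f"arrays metadata missing for columns: {sorted(missing)}")
        self.arrays = self.arrays.loc[list(self.values.columns)]
        for df in (self.values, self.detection_p):
            df.index.name = None
            df.columns.name = None

    # --- basic views -------------------------------------------------------
    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> List[str]:
        return list(self.values.columns)

    def control_arrays(self, batch=None) -> List[str]:
        meta = self.arrays
        mask = meta["condition"] == CONTROL
        if batch is not None:
            mask &= meta["batch"] == batch
        return list(meta.index[mask])

    def experiments(self) -> pd.DataFrame:
        """One row per knockdown experiment: experiment, condition, batch, arrays."""
        meta = self.arrays
        kd = meta[meta["condition"] != CONTROL]
        rows = []
        for (cond, batch), grp in kd.groupby(["condition", "batch"], sort=True):
            rows.append(
                {
                    "experiment": f"{cond}_b{batch}",
                    "condition": cond,
                    "batch": batch,
                    "arrays": list(grp.index),
                }
            )
        return pd.DataFrame(rows)

    def experiment_arrays(self, experiment: str) -> List[str]:
        exps = self.experiments().set_index("experiment")
        if experiment not in exps.index:
            raise KeyError(f"unknown experiment: {experiment}")
        return exps.loc[experiment, "arrays"]

    # --- transformations ---------------------------------------------------
    def subset_rows(self, rows) -> "ExpressionMatrix":
        rows = list(rows)
        return replace(
            self,
            values=self.values.loc[rows],
            detection_p=self.detection_p.loc[rows],
        )

    def subset_arrays(self, cols) -> "ExpressionMatrix":
        cols = list(cols)
        return ExpressionMatrix(
            values=self.values[cols],
            detection_p=self.detection_p[cols],
            arrays=self.arrays.loc[cols],
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        if not values.index.equals(self.values.index) or list(values.columns) != list(
            self.values.columns
        ):
            raise ValueError("replacement values must keep row/column labels")
        return replace(self, values=values)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.detection_p.copy(), self.arrays.copy()
        )
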