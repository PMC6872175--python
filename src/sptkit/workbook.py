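"""Readers for supplementary source-data spreadsheets.

Published per-track metric vectors are often distributed as xlsx workbooks
whose first sheet holds one labelled column per figure panel / experimental
group.  :func:`read_metric_workbook` loads such a sheet into a tidy
DataFrame of (group, value) rows so published medians and interquartile
ranges can be recomputed with :mod:`sptkit.stats`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class WorkbookSchemaError(ValueError):
    """Expected column labels absent from the workbook."""


def read_metric_workbook(path, sheet=0, expected_columns=None,
                         strict: bool = False) -> pd.DataFrame:
    """Read one sheet of metric vectors into long format.

    Each column is treated as one group's per-track metric values (header =
    group label); non-numeric cells are dropped.  ``expected_columns`` lists
    labels that must be present; with ``strict=True`` a missing label raises
    :class:`WorkbookSchemaError` instead of warning.
    """
    df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if expected_columns:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            msg = f"{path}: missing expected column(s) {', '.join(map(str, missing))}"
            if strict:
                raise WorkbookSchemaError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
    rows = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        rows.append(pd.DataFrame({"group": str(col), "value": vals}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["group", "value"])
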