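"""Reading and writing the package's tabular artifacts.

Scaling data travel as UTF-8 CSV with one judgment per row; ratio and
metric tables as CSV with a header; listener profiles and fitted parameters
as JSON.  Read-after-write is the identity on all tabular artifacts to
numerical tolerance.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

from .datatypes import (ScalingDataset, ScalingDatum, StimulusKind,
                        StimulusSpec, group_datasets)

__all__ = ["read_scaling_csv", "write_scaling_csv", "write_ratio_table",
           "read_ratio_table", "FormatError"]

_REQUIRED = ("listener", "kind", "presentation", "level_db", "response_cu")
_OPTIONAL = ("center_freq_hz", "azimuth_deg", "aided")


class FormatError(ValueError):
    """A file does not follow the expected schema."""


def read_scaling_csv(path) -> list[ScalingDataset]:
    """Read scaling datasets, grouped by (listener, stimulus, presentation).

    Malformed rows raise with the offending 0-based data row index.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            cf = row.get("center_freq_hz", np.nan)
            cf = None if (cf is None or (isinstance(cf, float) and math.isnan(cf))) else float(cf)
            stim = StimulusSpec(
                kind=StimulusKind(str(row["kind"])),
                center_freq_hz=cf,
                presentation=str(row["presentation"]),
                azimuth_deg=float(row.get("azimuth_deg", 0.0) or 0.0),
                aided=bool(row.get("aided", False)),
            )
            datum = ScalingDatum(level_db=float(row["level_db"]),
                                 response_cu=float(row["response_cu"]))
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: row {idx}: {exc}") from exc
        records.append((str(row["listener"]), stim, datum))
    return group_datasets(records)


def write_scaling_csv(datasets: list[ScalingDataset], path) -> None:
    rows = []
    for ds in datasets:
        st = ds.stimulus
        for d in ds.data:
            rows.append({
                "listener": ds.listener_id,
                "kind": st.kind.value,
                "center_freq_hz": st.center_freq_hz,
                "presentation": st.presentation.value,
                "azimuth_deg": st.azimuth_deg,
                "aided": st.aided,
                "level_db": d.level_db,
                "response_cu": d.response_cu,
            })
    pd.DataFrame(rows, columns=list(_REQUIRED[:3]) + list(_OPTIONAL)
                 + ["level_db", "response_cu"]
                 ).to_csv(path, index=False)


def write_ratio_table(table: pd.DataFrame, path) -> None:
    """Write a ratio/metric table; column order is preserved and a
    round-trip read returns identical values to 1e-9."""
    if not isinstance(table, pd.DataFrame):
        raise TypeError("table must be a pandas DataFrame")
    table.to_csv(path, index=False, float_format="%.12g")


def read_ratio_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
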