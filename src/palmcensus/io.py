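"""Read and write localization tables and census outputs.

Localization tables are plain CSV with a header, UTF-8, one row per
molecule.  Exports from localization software vary, so the reader
accepts common column aliases (``x``/``x_nm``, ``ch``/``channel``).
Channel labels are mapped to :class:`~palmcensus.core.Channel` through a
user-supplied mapping, e.g. ``{"CAGE500": Channel.CH_A, "CAGE552":
Channel.CH_B}`` for the EP2/OTR dye convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import Channel, Field

__all__ = [
    "LocFormatError",
    "ChannelMapError",
    "BoundsError",
    "read_localizations",
    "write_field",
    "write_census",
    "read_census",
]

_X_ALIASES = ("x", "x_nm", "x [nm]", "xnm")
_Y_ALIASES = ("y", "y_nm", "y [nm]", "ynm")
_CH_ALIASES = ("channel", "ch", "label", "dye")
_ID_ALIASES = ("id", "loc_id")


class LocFormatError(ValueError):
    """The CSV lacks a required column or is otherwise malformed."""


class ChannelMapError(ValueError):
    """A channel label in the file is not covered by the channel map."""


class BoundsError(ValueError):
    """A row's coordinates fall outside the stated ROI bounds."""


def _find_column(columns, aliases, what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    raise LocFormatError(
        f"no {what} column found; expected one of {aliases}, got {list(columns)}"
    )


def read_localizations(
    path,
    channel_map: Mapping[str, Channel],
    bounds: tuple[float, float] = (7000.0, 7000.0),
    meta: Mapping | None = None,
) -> Field:
    """Read a localization CSV into a :class:`Field`.

    Parameters
    ----------
    path : CSV file with header columns for x, y (nm) and a channel label.
    channel_map : mapping from every label present in the file to a Channel.
        Labels already equal to ``"CH_A"``/``"CH_B"`` are accepted as-is.
    bounds : (width, height) of the ROI in nm; rows outside are rejected.
    meta : free-form provenance labels attached to the Field.

    An ``id`` column, if present, is used verbatim; otherwise ids are
    assigned in row order.  Rows exactly on the boundary are accepted.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    xcol = _find_column(df.columns, _X_ALIASES, "x-coordinate")
    ycol = _find_column(df.columns, _Y_ALIASES, "y-coordinate")
    ccol = _find_column(df.columns, _CH_ALIASES, "channel")
    try:
        idcol = _find_column(df.columns, _ID_ALIASES, "id")
        ids = df[idcol].to_numpy(dtype=np.int64)
    except LocFormatError:
        ids = np.arange(len(df), dtype=np.int64)

    width, height = float(bounds[0]), float(bounds[1])
    x = df[xcol].to_numpy(dtype=np.float64)
    y = df[ycol].to_numpy(dtype=np.float64)

    channels = np.empty(len(df), dtype=np.uint8)
    lookup = {str(k): v for k, v in channel_map.items()}
    for ch in Channel:  # pass-through of canonical names
        lookup.setdefault(ch.name, ch)
    for i, label in enumerate(df[ccol].astype(str)):
        try:
            channels[i] = lookup[label].value
        except KeyError:
            raise ChannelMapError(
                f"row {i}: channel label {label!r} not in channel map "
                f"{sorted(lookup)}"
            ) from None

    bad = np.flatnonzero((x < 0) | (x > width) | (y < 0) | (y > height))
    if bad.size:
        i = int(bad[0])
        raise BoundsError(
            f"row {i} (id={ids[i]}): coordinate ({x[i]:g}, {y[i]:g}) nm outside "
            f"bounds {width:g} x {height:g} nm"
        )
    return Field(
        ids=ids,
        channels=channels,
        xy=np.column_stack([x, y]) if len(df) else np.empty((0, 2)),
        width=width,
        height=height,
        meta=dict(meta or {}),
    )


def write_field(field: Field, path) -> None:
    """Write a Field as CSV (columns id, channel, x_nm, y_nm) in id order.

    ``read_localizations(write_field(f))`` reproduces ``f`` exactly:
    coordinates are written with full float precision.
    """
    order = np.argsort(field.ids, kind="stable")
    df = pd.DataFrame(
        {
            "id": field.ids[order],
            "channel": [Channel(int(c)).name for c in field.channels[order]],
            "x_nm": field.xy[order, 0],
            "y_nm": field.xy[order, 1],
        }
    )
    # 17 significant digits -> exact float round trip
    df.to_csv(path, index=False, float_format="%.17g")


def write_census(summary, path) -> None:
    """Write a :class:`~palmcensus.census.CensusSummary`.

    Emits a TSV of per-field metrics (one row per field × metric) at
    ``path`` and a JSON sidecar (``path`` with a ``.json`` suffix) of
    condition-level means/SEM across experiments.
    """
    path = Path(path)
    summary.per_field.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(".json")
    records = {}
    for cond, sub in summary.per_condition.groupby("condition", sort=True):
        records[cond] = {
            row.metric: {
                "mean": row.mean_,
                "sem": None if pd.isna(row.sem) else row.sem,
                "n_experiments": int(row.n_experiments),
            }
            for row in sub.rename(columns={"mean": "mean_"}).itertuples()
        }
    sidecar.write_text(json.dumps(records, indent=1, sort_keys=True))


def read_census(path):
    """Read back a census written by :func:`write_census` (round-trip aid)."""
    from .census import CensusSummary

    path = Path(path)
    per_field = pd.read_csv(path, sep="\t", float_precision="round_trip")
    raw = json.loads(path.with_suffix(".json").read_text())
    rows = []
    for cond, metrics in raw.items():
        for metric, entry in metrics.items():
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "mean": entry["mean"],
                    "sem": np.nan if entry["sem"] is None else entry["sem"],
                    "n_experiments": entry["n_experiments"],
                }
            )
    per_condition = pd.DataFrame(
        rows, columns=["condition", "metric", "mean", "sem", "n_experiments"]
    )
    return CensusSummary(per_field=per_field, per_condition=per_condition)
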