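"""Core containers for dual-color single-molecule localization data.

A :class:`Field` is one imaged region of interest (by convention a
7 µm × 7 µm window inside a cell's membrane footprint) holding the
localized molecule positions from both color channels.  All coordinates
are in nanometers, origin at the lower-left corner of the ROI, y
increasing upward.  Only inter-point distances matter downstream, so the
convention is internal, but it is fixed and documented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Channel", "Localization", "Field"]


class Channel(Enum):
    """Color channel identity of a localization.

    Semantic mapping follows the two-receptor labeling convention:
    ``CH_A`` is the EP2 receptor channel (CAGE 500 dye) and ``CH_B`` the
    oxytocin receptor channel (CAGE 552 dye).
    """

    CH_A = 0
    CH_B = 1

    @property
    def receptor(self) -> str:
        return "EP2" if self is Channel.CH_A else "OTR"


@dataclass(frozen=True)
class Localization:
    """One detected molecule: planar position (nm) plus channel identity."""

    id: int
    channel: Channel
    x: float
    y: float


@dataclass
class Field:
    """A bounded ROI containing the localizations of one imaged area.

    Data are stored columnar (numpy arrays) for fast neighbor queries;
    :meth:`__iter__` yields :class:`Localization` records for convenience.

    Parameters
    ----------
    ids : integer array, unique within the field
    channels : uint8 array, ``Channel`` values (0 = CH_A, 1 = CH_B)
    xy : (n, 2) float array of positions in nm
    width, height : ROI extent in nm (default 7000 × 7000)
    meta : free-form labels (cell id, experiment id, condition, ...)
    """

    ids: np.ndarray
    channels: np.ndarray
    xy: np.ndarray
    width: float = 7000.0
    height: float = 7000.0
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.xy = np.asarray(self.xy, dtype=np.float64).reshape(-1, 2)
        n = len(self.ids)
        if len(self.channels) != n or len(self.xy) != n:
            raise ValueError("ids, channels and xy must have equal length")
        if n and len(np.unique(self.ids)) != n:
            raise ValueError("localization ids must be unique within a field")
        if not np.all(np.isin(self.channels, (0, 1))):
            raise ValueError("channels must be 0 (CH_A) or 1 (CH_B)")
        if n and not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        # closed interval: points exactly on the boundary are legal
        if n and (
            self.xy[:, 0].min() < 0
            or self.xy[:, 1].min() < 0
            or self.xy[:, 0].max() > self.width
            or self.xy[:, 1].max() > self.height
        ):
            bad = int(
                np.flatnonzero(
                    (self.xy[:, 0] < 0)
                    | (self.xy[:, 0] > self.width)
                    | (self.xy[:, 1] < 0)
                    | (self.xy[:, 1] > self.height)
                )[0]
            )
            raise ValueError(
                f"localization id={self.ids[bad]} at "
                f"({self.xy[bad, 0]:g}, {self.xy[bad, 1]:g}) nm lies outside "
                f"the {self.width:g} x {self.height:g} nm ROI"
            )

    @classmethod
    def from_localizations(
        cls,
        locs: "list[Localization]",
        width: float = 7000.0,
        height: float = 7000.0,
        meta: Mapping | None = None,
    ) -> "Field":
        return cls(
            ids=np.array([l.id for l in locs], dtype=np.int64),
            channels=np.array([l.channel.value for l in locs], dtype=np.uint8),
            xy=np.array([[l.x, l.y] for l in locs], dtype=np.float64).reshape(-1, 2),
            width=width,
            height=height,
            meta=dict(meta or {}),
        )

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[Localization]:
        for i in range(len(self.ids)):
            yield Localization(
                id=int(self.ids[i]),
                channel=Channel(int(self.channels[i])),
                x=float(self.xy[i, 0]),
                y=float(self.xy[i, 1]),
            )

    def subset(self, mask: np.ndarray) -> "Field":
        """Return a new Field restricted to ``mask`` (bool or index array)."""
        return Field(
            ids=self.ids[mask],
            channels=self.channels[mask],
            xy=self.xy[mask],
            width=self.width,
            height=self.height,
            meta=dict(self.meta),
        )

    def equals(self, other: "Field") -> bool:
        return (
            self.width == other.width
            and self.height == other.height
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.channels, other.channels)
            and np.array_equal(self.xy, other.xy)
        )
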