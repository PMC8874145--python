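"""Core in-memory container for list-mode cytometry data.

An :class:`EventTable` holds an events-by-channels float matrix together with
the ordered channel names and a flat string keyword map (the FCS TEXT-segment
metadata).  An optional per-event ``labels`` array carries ground-truth
population assignments for synthetic data; it is never written to FCS files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventTable"]


@dataclass
class EventTable:
    """Events-by-channels matrix with acquisition metadata.

    Parameters
    ----------
    channels
        Ordered detector/parameter names (e.g. ``FSC-A``, ``SSC-A``, ``PE-A``).
    events
        Float array of shape ``(n_events, n_channels)``.
    keywords
        Flat string map of FCS keywords (``$TOT``, experiment name, well,
        reagent identifiers, ...).
    labels
        Optional per-event ground-truth population label (synthetic data only).
    """

    channels: list[str]
    events: np.ndarray
    keywords: dict[str, str] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim == 1:
            self.events = self.events.reshape(0, len(self.channels))
        if self.events.ndim != 2 or self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"event matrix has {self.events.shape[1] if self.events.ndim == 2 else '?'} "
                f"columns but {len(self.channels)} channel names were given"
            )
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("event values must be finite")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.events.shape[0]:
                raise ValueError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channels}") from None

    def column(self, name: str) -> np.ndarray:
        """Values of one channel, shape ``(n_events,)``."""
        return self.events[:, self.channel_index(name)]

    def with_events(self, events: np.ndarray, **kw_updates: str) -> "EventTable":
        """Copy with replaced event matrix (same channels) and updated keywords."""
        keywords = dict(self.keywords)
        keywords.update(kw_updates)
        return EventTable(list(self.channels), events, keywords, labels=self.labels)

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row-subset by boolean mask; labels follow the events."""
        labels = self.labels[mask] if self.labels is not None else None
        return EventTable(list(self.channels), self.events[mask], dict(self.keywords), labels=labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=self.channels)
        if self.labels is not None:
            df["__label__"] = self.labels
        return df
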