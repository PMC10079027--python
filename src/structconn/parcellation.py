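"""Parcellation: the ordered table of labeled brain structures that defines
connectome nodes.

A parcellation assigns every structure a positive integer label (0 is reserved
for background voxels), a name, and a volume in mm^3.  The row order of the
table is the canonical node order for every connectivity matrix built against
it.  A subset of structures may be flagged as hubs (e.g. a brainstem-like
structure) and each structure belongs to a community (used by the synthetic
generator's block model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_COLUMNS = ["label_id", "name", "volume_mm3", "is_hub", "community"]


@dataclass(frozen=True)
class Parcellation:
    """Ordered structure table defining connectome nodes.

    Parameters
    ----------
    table:
        DataFrame with columns ``label_id`` (unique positive int), ``name``
        (str), ``volume_mm3`` (float > 0), ``is_hub`` (bool), ``community``
        (int).  Row order is the canonical node order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns {missing}")
        labels = t["label_id"].to_numpy()
        if len(labels) == 0:
            raise ValueError("parcellation must contain at least one region")
        if labels.min() < 1:
            raise ValueError("label_ids must be positive (0 is background)")
        if len(np.unique(labels)) != len(labels):
            raise ValueError("label_ids must be unique")
        if (t["volume_mm3"].to_numpy() <= 0).any():
            raise ValueError("volumes must be strictly positive")

    # -- convenience views -------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        """Canonical node order, as label ids."""
        return self.table["label_id"].to_numpy(dtype=np.int64)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def volumes(self) -> np.ndarray:
        return self.table["volume_mm3"].to_numpy(dtype=float)

    @property
    def communities(self) -> np.ndarray:
        return self.table["community"].to_numpy(dtype=np.int64)

    @property
    def hub_labels(self) -> np.ndarray:
        return self.table.loc[self.table["is_hub"], "label_id"].to_numpy(dtype=np.int64)

    def volume_of(self) -> dict[int, float]:
        """Map label_id -> volume (mm^3)."""
        return dict(zip(self.labels.tolist(), self.volumes.tolist()))

    def name_of(self) -> dict[int, str]:
        return dict(zip(self.labels.tolist(), self.names))

    def subset(self, keep_labels) -> "Parcellation":
        """Return the parcellation restricted to ``keep_labels``, preserving
        canonical order."""
        keep = set(int(x) for x in keep_labels)
        unknown = keep - set(self.labels.tolist())
        if unknown:
            raise ValueError(f"labels not in parcellation: {sorted(unknown)}")
        mask = self.table["label_id"].isin(keep)
        return Parcellation(self.table.loc[mask].reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.table[_COLUMNS].copy()
        out["is_hub"] = out["is_hub"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Parcellation":
        t = pd.read_csv(Path(path))
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        t = t[_COLUMNS].copy()
        t["is_hub"] = t["is_hub"].astype(bool)
        return cls(t)
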