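"""Packaged atlas fixtures: extended (104-structure) and restricted
(84-structure) node sets plus the 20-structure removal list.

These are SYNTHETIC stand-ins, not transcriptions: the structure names
follow the standard FreeSurfer aseg/aparc (Desikan-Killiany) convention —
68 cortical parcels, 14 subcortical nuclei and both cerebellar cortices in
the restricted set; the brainstem, ventral diencephalon, cerebral and
cerebellar white matter, ventricles, CSF, choroid plexus, vessels, optic
chiasm and WM hypointensities form the 20 structures present only in the
extended set — and the volumes are plausible synthetic averages, since
per-subject anatomy is not redistributable.  The brainstem is flagged as
the hub.  Node-set arithmetic (104 - 20 = 84) is exact by construction.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .parcellation import Parcellation

__all__ = [
    "extended_parcellation",
    "restricted_parcellation",
    "removed_structure_names",
    "removed_structure_labels",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("structconn").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def extended_parcellation() -> Parcellation:
    """104-structure node set including the brainstem (synthetic volumes)."""
    t = _load("extended_structures_synthetic.csv").copy()
    t["is_hub"] = t["is_hub"].astype(bool)
    return Parcellation(t[["label_id", "name", "volume_mm3", "is_hub", "community"]])


def restricted_parcellation() -> Parcellation:
    """84-structure Desikan-Killiany-style node set (brainstem excluded)."""
    t = _load("restricted_structures_synthetic.csv").copy()
    t["is_hub"] = t["is_hub"].astype(bool)
    return Parcellation(t[["label_id", "name", "volume_mm3", "is_hub", "community"]])


def removed_structure_names() -> list[str]:
    """The 20 structures present only in the extended node set."""
    t = _load("extended_structures_synthetic.csv")
    return t.loc[t["removed_in_restricted"] == 1, "name"].tolist()


def removed_structure_labels() -> list[int]:
    t = _load("extended_structures_synthetic.csv")
    return t.loc[t["removed_in_restricted"] == 1, "label_id"].astype(int).tolist()
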