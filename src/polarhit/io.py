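"""Reading and writing cohort files.

Clinical covariates and outcomes travel as CSV (one row per patient, missing
values as empty cells); polar-map stacks travel as HDF5 with one ``float``
dataset of shape 5 x 28 x 36 per patient, on the 0-100 scale, channel order
(perfusion, motion, thickening, phase, amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import CLINICAL_FEATURES, EVENT_NAMES, EventKind

__all__ = ["Cohort", "MAP_SHAPE", "CHANNEL_NAMES", "read_cohort", "write_cohort"]

MAP_SHAPE = (5, 28, 36)
CHANNEL_NAMES = ("perfusion", "motion", "thickening", "phase", "amplitude")


@dataclass
class Cohort:
    """In-memory cohort: ids, clinical table, polar-map stacks, outcomes.

    ``clinical`` is indexed by patient id with the 15 feature columns;
    ``maps`` is an ``(n, 5, 28, 36)`` array aligned with ``ids``;
    ``outcomes`` has columns ``event_kind`` (names) and ``time_days``.
    """

    ids: np.ndarray
    clinical: pd.DataFrame
    maps: np.ndarray
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.clinical) != n or len(self.outcomes) != n:
            raise ValueError("ids, clinical and outcomes must align")
        if self.maps.shape != (n, *MAP_SHAPE):
            raise ValueError(
                f"maps must have shape {(n, *MAP_SHAPE)}, got {self.maps.shape}"
            )

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask_or_index) -> "Cohort":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Cohort(
            ids=self.ids[idx],
            clinical=self.clinical.iloc[idx],
            maps=self.maps[idx],
            outcomes=self.outcomes.iloc[idx].reset_index(drop=True),
        )


def write_cohort(cohort: Cohort, clinical_csv, maps_h5, outcomes_csv) -> None:
    clin = cohort.clinical.copy()
    clin.insert(0, "patient_id", cohort.ids)
    clin.to_csv(clinical_csv, index=False)

    out = cohort.outcomes.copy()
    out.insert(0, "patient_id", cohort.ids)
    out.to_csv(outcomes_csv, index=False)

    with h5py.File(maps_h5, "w") as f:
        f.attrs["channel_names"] = list(CHANNEL_NAMES)
        for pid, stack in zip(cohort.ids, cohort.maps):
            f.create_dataset(str(pid), data=np.asarray(stack, dtype=np.float32))


def read_cohort(clinical_csv, maps_h5, outcomes_csv) -> Cohort:
    clin = pd.read_csv(clinical_csv)
    ids = clin["patient_id"].to_numpy()
    clin = clin.set_index("patient_id")
    missing = [c for c in CLINICAL_FEATURES if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical file is missing feature columns: {missing}")
    clin = clin[list(CLINICAL_FEATURES)]

    out = pd.read_csv(outcomes_csv)
    out = out.set_index("patient_id").loc[ids].reset_index()
    valid = set(EVENT_NAMES.values())
    bad = set(out["event_kind"].unique()) - valid
    if bad:
        raise ValueError(f"unknown event kinds in outcomes file: {sorted(bad)}")
    out = out[["event_kind", "time_days"]]

    with h5py.File(maps_h5, "r") as f:
        maps = np.empty((len(ids), *MAP_SHAPE), dtype=np.float64)
        for i, pid in enumerate(ids):
            ds = f[str(pid)][()]
            if ds.shape != MAP_SHAPE:
                raise ValueError(
                    f"polar map for patient {pid} has shape {ds.shape}, "
                    f"expected {MAP_SHAPE}"
                )
            maps[i] = ds
        if np.isnan(maps).any():
            raise ValueError("polar maps contain missing pixels")

    return Cohort(ids=ids, clinical=clin, maps=maps, outcomes=out)
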