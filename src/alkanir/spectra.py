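"""In-memory containers and CSV contracts for spectra and alkane tables.

A :class:`SpectraSet` holds log(1/R) absorbance spectra of excreta samples on a
shared, strictly increasing wavenumber grid (cm^-1).  Alkane concentration
tables (mg/kg DM) are plain :class:`pandas.DataFrame` objects indexed by
``sample_id`` with one column per alkane (C25, C27, C29, C31, C33); the same
layout serves the three roles in the mixing model — feed (F), alfalfa (A) and
excreta (E).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ALKANES = ("C25", "C27", "C29", "C31", "C33")

CONTROL = "control"
ALFALFA = "alfalfa"


@dataclass
class SpectraSet:
    """Absorbance matrix on a shared wavenumber grid.

    Parameters
    ----------
    wavenumbers : array, shape (p,)
        Strictly increasing grid in cm^-1.
    absorbance : array, shape (n, p)
        log(1/R) per sample, no missing values.
    sample_ids : array of str, shape (n,)
        Unique identifiers, one row per sample.
    diet_group : array of str, shape (n,), optional
        Diet label per sample (``control`` / ``alfalfa``).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    diet_group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.diet_group is not None:
            self.diet_group = np.asarray(self.diet_group, dtype=object)
            if len(self.diet_group) != len(self.sample_ids):
                raise ValueError("diet_group length does not match sample_ids")
        if self.absorbance.shape != (len(self.sample_ids), len(self.wavenumbers)):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.wavenumbers)} wavenumbers"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def step(self) -> float:
        """Grid step; raises if the grid is not uniform (tolerance 1e-9)."""
        d = np.diff(self.wavenumbers)
        if d.size and not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise ValueError("wavenumber grid is not uniform")
        return float(d[0]) if d.size else 0.0

    def with_absorbance(self, absorbance: np.ndarray,
                        wavenumbers: np.ndarray | None = None) -> "SpectraSet":
        """Copy with new absorbance (and optionally a new grid)."""
        return replace(
            self,
            absorbance=absorbance,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
        )

    def subset(self, sample_ids) -> "SpectraSet":
        """Row subset in the order given by ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        rows = np.array([index[s] for s in sample_ids])
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[rows],
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            diet_group=None if self.diet_group is None else self.diet_group[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide frame: sample_id index, one column per wavenumber."""
        return pd.DataFrame(
            self.absorbance,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[format(w, "g") for w in self.wavenumbers],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, animals: pd.DataFrame | None = None) -> "SpectraSet":
        """Read the wide CSV; optionally attach diet groups from an animals table."""
        frame = pd.read_csv(path, index_col="sample_id")
        ids = frame.index.to_numpy(dtype=object)
        groups = None
        if animals is not None:
            groups = animals.loc[ids, "diet_group"].to_numpy(dtype=object)
        return cls(
            wavenumbers=frame.columns.to_numpy(dtype=float),
            absorbance=frame.to_numpy(dtype=float),
            sample_ids=ids,
            diet_group=groups,
        )


def validate_alkane_table(table: pd.DataFrame, alkanes=ALKANES) -> pd.DataFrame:
    """Check an alkane concentration table and return it with canonical column order."""
    missing = [a for a in alkanes if a not in table.columns]
    if missing:
        raise ValueError(f"alkane table missing columns: {missing}")
    out = table.loc[:, list(alkanes)]
    if not np.all(np.isfinite(out.to_numpy(dtype=float))):
        raise ValueError("alkane table contains non-finite values")
    if (out.to_numpy() < 0).any():
        raise ValueError("alkane concentrations must be >= 0")
    return out


def read_alkane_csv(path, alkanes=ALKANES) -> pd.DataFrame:
    return validate_alkane_table(pd.read_csv(path, index_col="sample_id"), alkanes)


def write_alkane_csv(table: pd.DataFrame, path) -> None:
    table.rename_axis("sample_id").to_csv(path)
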