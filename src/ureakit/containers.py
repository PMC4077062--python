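"""Shared in-memory containers used across the analysis stages.

The containers are deliberately light: a :class:`StructureModel` is a flat
atom table (numpy arrays), an :class:`UptakeDataset` wraps a tidy pandas
frame of replicated measurements, and :class:`CensoredValue` carries a
kinetic constant that the assay range only bounds (e.g. ``">3000"`` µM).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BACKBONE_ATOMS",
    "CensoredValue",
    "StructureModel",
    "UptakeDataset",
    "CandidateResidue",
]

#: Protein backbone atom names; everything else on a residue counts as sidechain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class CensoredValue:
    """A constant known only to one side of a bound, e.g. Ki ``">3000"`` µM.

    Parameters
    ----------
    bound:
        The numeric bound in the constant's own units.
    op:
        ``">"`` for lower-bounded ("beyond the tested range"), ``"<"`` for
        upper-bounded (below assay resolution).
    """

    bound: float
    op: Literal[">", "<"] = ">"

    def __post_init__(self) -> None:
        if self.op not in (">", "<"):
            raise ValueError(f"censoring operator must be '>' or '<', got {self.op!r}")
        if not np.isfinite(self.bound):
            raise ValueError("censoring bound must be finite")

    def __str__(self) -> str:  # e.g. ">3000"
        bound = self.bound
        text = f"{bound:g}"
        return f"{self.op}{text}"

    @classmethod
    def parse(cls, text: str) -> "CensoredValue":
        text = text.strip()
        if not text or text[0] not in "<>":
            raise ValueError(f"not a censored value: {text!r}")
        return cls(bound=float(text[1:]), op=text[0])  # type: ignore[arg-type]


def parse_maybe_censored(text: str) -> float | CensoredValue:
    """Parse a table cell that is either a number or a censored bound."""
    text = str(text).strip()
    if text and text[0] in "<>":
        return CensoredValue.parse(text)
    return float(text)


@dataclass(frozen=True)
class CandidateResidue:
    """A reference-numbered residue position with its conservation class.

    ``ref_position`` is 1-based on the ungapped reference sequence, matching
    the field's residue naming convention (Y106, S446, ...). Downstream
    stages attach topology, exposure and polarity annotations.
    """

    ref_position: int
    ref_residue: str
    conservation_class: str
    topology_label: str | None = None
    exposed: bool | None = None
    polar: bool | None = None

    @property
    def name(self) -> str:
        """Residue name in one-letter + position form, e.g. ``Y106``."""
        return f"{self.ref_residue}{self.ref_position}"


class StructureModel:
    """Atoms of a 3D protein model: residue numbering, names and Å coordinates.

    A thin column-oriented table. Residue numbers follow author numbering of
    the source PDB; coordinates are Ångström.
    """

    def __init__(
        self,
        res_ids: Sequence[int],
        res_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
    ) -> None:
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype=object)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.res_ids)
        if not (len(self.res_names) == len(self.atom_names) == len(self.elements) == len(self.coords) == n):
            raise ValueError("atom columns must have equal length")
        if n == 0:
            raise ValueError("a structure model needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.res_ids < 1):
            raise ValueError("residue numbers must be positive")

    def __len__(self) -> int:
        return len(self.res_ids)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers present in the model."""
        return np.unique(self.res_ids)

    def residue_name(self, res_id: int) -> str:
        mask = self.res_ids == res_id
        if not mask.any():
            raise KeyError(f"residue {res_id} not in model")
        return str(self.res_names[mask][0])

    def atom_mask(self, res_id: int, sidechain_only: bool = False) -> np.ndarray:
        mask = self.res_ids == res_id
        if sidechain_only:
            is_side = np.array([a not in BACKBONE_ATOMS for a in self.atom_names])
            mask = mask & is_side
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (used for invariance checks)."""
        coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(self.res_ids, self.res_names, self.atom_names, self.elements, coords)

    # -- PDB I/O ---------------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        """Write minimal ATOM records (Å, author numbering)."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arr = struc.AtomArray(len(self))
        arr.coord = self.coords
        arr.res_id = self.res_ids
        arr.res_name = np.array([str(r)[:3] for r in self.res_names], dtype="U5")
        arr.atom_name = np.array([str(a) for a in self.atom_names], dtype="U6")
        arr.element = np.array([str(e) for e in self.elements], dtype="U2")
        arr.chain_id = np.full(len(self), "A", dtype="U4")
        arr.hetero = np.zeros(len(self), dtype=bool)
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        return (
            np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.res_names, other.res_names)
            and np.array_equal(self.atom_names, other.atom_names)
            and np.allclose(self.coords, other.coords, atol=1e-3)
        )


_KINDS = ("timecourse", "saturation", "competition")


@dataclass
class UptakeDataset:
    """Replicated radiotracer uptake measurements.

    ``data`` is a tidy frame with columns ``x`` (minutes for time courses,
    µM for concentration series), ``replicate`` and ``signal`` (pmol per
    10^7 conidiospores, or any linear count scale). ``tracer_conc`` is the
    labelled-substrate concentration L in µM (competition assays).
    """

    kind: str
    condition: str
    data: pd.DataFrame
    tracer_conc: float | None = None
    dataset_id: str = "ds"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        required = {"x", "replicate", "signal"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        x = self.data["x"].to_numpy(float)
        if self.kind in ("saturation", "competition") and np.any(x <= 0) and self.kind == "saturation":
            raise ValueError("concentrations must be strictly positive")
        if self.kind == "timecourse" and np.any(x < 0):
            raise ValueError("time points must be non-negative")

    @property
    def x_values(self) -> np.ndarray:
        return np.unique(self.data["x"].to_numpy(float))

    def means(self) -> pd.Series:
        """Replicate-mean signal indexed by x."""
        return self.data.groupby("x")["signal"].mean()

    def replicate_cv(self) -> pd.Series:
        """Replicate coefficient of variation (SD/mean) per x."""
        g = self.data.groupby("x")["signal"]
        return g.std(ddof=1) / g.mean()

    # -- TSV I/O ---------------------------------------------------------

    _X_COL = {"timecourse": "time_min", "saturation": "conc_uM", "competition": "conc_uM"}

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.rename(columns={"x": self._X_COL[self.kind]}).copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "dataset_id", self.dataset_id)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str, tracer_conc: float | None = None) -> "UptakeDataset":
        df = pd.read_csv(path, sep="\t")
        x_col = cls._X_COL.get(kind)
        if x_col not in df.columns:
            raise ValueError(f"expected column {x_col!r} for a {kind} dataset")
        condition = str(df["condition"].iloc[0]) if "condition" in df.columns else "unknown"
        dataset_id = str(df["dataset_id"].iloc[0]) if "dataset_id" in df.columns else "ds"
        data = df.rename(columns={x_col: "x"})[["x", "replicate", "signal"]]
        return cls(kind=kind, condition=condition, data=data, tracer_conc=tracer_conc, dataset_id=dataset_id)
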