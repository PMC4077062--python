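"""Structural filters on a transporter model: SASA, exposure, polarity,
residue-pair geometry and salt bridges.

The accessibility engine is Shrake–Rupley: each atom's sphere is expanded
by the probe radius, sampled with a deterministic quasi-uniform point set,
and the accessible fraction is the fraction of points not inside any other
expanded sphere. The default probe is 2.0 Å, the probe used for the cavity
surface of the transporter model this pipeline was built around; a 1.4 Å
water probe is available through the ``probe_radius`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .containers import BACKBONE_ATOMS, CandidateResidue, StructureModel
from .residues import MAX_ASA_SIDECHAIN, POLAR_RESIDUES, VDW_RADII, one_letter, three_letter

__all__ = [
    "read_structure",
    "sasa",
    "SASAResult",
    "cavity_exposed",
    "polar_filter",
    "pathway_candidates",
    "PathwayResult",
    "pair_facing",
    "FacingResult",
    "find_salt_bridges",
    "SaltBridge",
]


def read_structure(path: str | Path, include_hetero: bool = False) -> StructureModel:
    """Read ATOM records from a PDB file into a :class:`StructureModel`.

    HETATM records and waters are excluded by default. Duplicate atoms
    (same residue number and atom name) trigger a warning; the first
    occurrence is kept.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    if not include_hetero:
        arr = arr[~arr.hetero]
        arr = arr[arr.res_name != "HOH"]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records (empty model)")

    seen: set[tuple[int, str]] = set()
    keep = np.ones(arr.array_length(), dtype=bool)
    for i in range(arr.array_length()):
        key = (int(arr.res_id[i]), str(arr.atom_name[i]))
        if key in seen:
            warnings.warn(f"duplicate atom {key} in {path}; keeping first occurrence")
            keep[i] = False
        seen.add(key)
    arr = arr[keep]
    return StructureModel(
        res_ids=arr.res_id,
        res_names=[str(r) for r in arr.res_name],
        atom_names=[str(a) for a in arr.atom_name],
        elements=[str(e) for e in arr.element],
        coords=arr.coord,
    )


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(
    model: StructureModel, on_unknown: Literal["default", "fail"], default_radius: float
) -> np.ndarray:
    radii = np.empty(len(model))
    for i, el in enumerate(model.elements):
        key = str(el).upper()
        if key in VDW_RADII:
            radii[i] = VDW_RADII[key]
        elif on_unknown == "fail":
            raise KeyError(f"no van der Waals radius for element {el!r}")
        else:
            warnings.warn(f"no van der Waals radius for element {el!r}; using {default_radius} Å")
            radii[i] = default_radius
    return radii


@dataclass
class SASAResult:
    """Per-atom and per-residue solvent accessible surface areas (Å²).

    ``relative_sidechain`` normalises each residue's sidechain area by a
    maximum-accessibility reference (tripeptide theoretical maxima); glycine
    uses its Cα area against a Cα reference instead.
    """

    model: StructureModel
    probe_radius: float
    per_atom: np.ndarray
    per_residue_total: dict[int, float]
    per_residue_sidechain: dict[int, float]
    relative_sidechain: dict[int, float]


def sasa(
    model: StructureModel,
    probe_radius: float = 2.0,
    n_sphere_points: int = 960,
    on_unknown_element: Literal["default", "fail"] = "default",
    default_radius: float = 1.70,
) -> SASAResult:
    """Shrake–Rupley solvent accessible surface area.

    For each atom the accessible area is the fraction of ``n_sphere_points``
    on its expanded sphere (r_vdW + probe) lying outside every other expanded
    sphere, times 4π(r_vdW + probe)².
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if n_sphere_points < 1:
        raise ValueError("need at least one sphere point")
    radii = _atom_radii(model, on_unknown_element, default_radius) + probe_radius
    coords = model.coords
    n = len(model)
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2

    per_residue_total: dict[int, float] = {}
    per_residue_sidechain: dict[int, float] = {}
    relative: dict[int, float] = {}
    is_side = np.array([a not in BACKBONE_ATOMS for a in model.atom_names])
    for res_id in model.residue_ids:
        mask = model.res_ids == res_id
        per_residue_total[int(res_id)] = float(per_atom[mask].sum())
        side = mask & is_side
        per_residue_sidechain[int(res_id)] = float(per_atom[side].sum())
        name = str(model.res_names[mask][0]).upper()
        if name == "GLY":
            ca = mask & (model.atom_names == "CA")
            area = float(per_atom[ca].sum())
        else:
            area = per_residue_sidechain[int(res_id)]
        ref = MAX_ASA_SIDECHAIN.get(name)
        relative[int(res_id)] = area / ref if ref else float("nan")
    return SASAResult(
        model=model,
        probe_radius=probe_radius,
        per_atom=per_atom,
        per_residue_total=per_residue_total,
        per_residue_sidechain=per_residue_sidechain,
        relative_sidechain=relative,
    )


def cavity_exposed(result: SASAResult, res_id: int, threshold: float = 0.15) -> bool:
    """True iff the residue's relative sidechain accessibility >= threshold.

    Glycine, lacking a sidechain, is judged on its Cα accessibility (already
    folded into ``relative_sidechain``).
    """
    if int(res_id) not in result.relative_sidechain:
        raise KeyError(f"residue {res_id} not present in the SASA result")
    return result.relative_sidechain[int(res_id)] >= threshold


# ---------------------------------------------------------------------------
# polarity and the combined pathway filter
# ---------------------------------------------------------------------------


def _residue_code(item: object) -> str:
    """Extract a 1-letter residue code from flexible inputs.

    Accepts 1-/3-letter codes ("Y", "TYR"), field-style names ("Y106"),
    and :class:`CandidateResidue`.
    """
    if isinstance(item, CandidateResidue):
        return one_letter(item.ref_residue)
    text = str(item).strip()
    alpha = "".join(ch for ch in text if ch.isalpha())
    if len(alpha) == 3:
        return one_letter(alpha)
    if len(alpha) == 1:
        return one_letter(alpha)
    raise KeyError(f"cannot resolve residue name from {text!r}")


def polar_filter(residues: Sequence[object]) -> list[object]:
    """Keep residues whose sidechain can hydrogen-bond with a urea molecule.

    Default polar set: S, T, C, Y, N, Q, D, E, K, R, H, W.
    """
    return [r for r in residues if _residue_code(r) in POLAR_RESIDUES]


@dataclass
class PathwayResult:
    """Outcome of the conserved + exposed + polar pathway filter."""

    candidates: list[CandidateResidue]
    unevaluable: list[CandidateResidue]  # positions outside the modelled range


def pathway_candidates(
    model: StructureModel,
    sasa_result: SASAResult,
    family_conserved: Sequence[CandidateResidue],
    threshold: float = 0.15,
) -> PathwayResult:
    """Intersect the three substrate-pathway filters.

    A position passes when it is (i) in the supplied family-conserved set,
    (ii) solvent exposed in the model at the given relative-accessibility
    threshold, and (iii) polar. Positions absent from the model (outside
    the modelled range) are reported as unevaluable, never silently dropped.
    """
    present = set(int(r) for r in model.residue_ids)
    kept: list[CandidateResidue] = []
    unevaluable: list[CandidateResidue] = []
    for cand in sorted(family_conserved, key=lambda c: c.ref_position):
        if cand.ref_position not in present:
            unevaluable.append(cand)
            continue
        exposed = cavity_exposed(sasa_result, cand.ref_position, threshold)
        polar = one_letter(cand.ref_residue) in POLAR_RESIDUES
        if exposed and polar:
            kept.append(
                CandidateResidue(
                    ref_position=cand.ref_position,
                    ref_residue=cand.ref_residue,
                    conservation_class=cand.conservation_class,
                    exposed=True,
                    polar=True,
                )
            )
    return PathwayResult(candidates=kept, unevaluable=unevaluable)


# ---------------------------------------------------------------------------
# residue-pair geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FacingResult:
    facing: bool
    centroid_distance: float
    angle_a: float  # degrees between Cα_a→centroid_a and Cα_a→centroid_b
    angle_b: float


def _sidechain_centroid(model: StructureModel, res_id: int) -> tuple[np.ndarray, np.ndarray]:
    side = model.atom_mask(res_id, sidechain_only=True)
    if not side.any():
        raise ValueError(f"residue {res_id} has no sidechain atoms")
    ca_mask = model.atom_mask(res_id) & (model.atom_names == "CA")
    if not ca_mask.any():
        raise ValueError(f"residue {res_id} has no CA atom")
    return model.coords[side].mean(axis=0), model.coords[ca_mask][0]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pair_facing(
    model: StructureModel,
    res_a: int,
    res_b: int,
    distance_cutoff: float = 8.0,
    angle_cutoff: float = 60.0,
) -> FacingResult:
    """Do two sidechains point at each other across a cavity?

    True iff the sidechain centroids are within ``distance_cutoff`` Å and,
    for each residue, the Cα→own-centroid vector points toward the *other*
    residue's centroid within ``angle_cutoff`` degrees.
    """
    cen_a, ca_a = _sidechain_centroid(model, res_a)
    cen_b, ca_b = _sidechain_centroid(model, res_b)
    distance = float(np.linalg.norm(cen_a - cen_b))
    angle_a = _angle_deg(cen_a - ca_a, cen_b - ca_a)
    angle_b = _angle_deg(cen_b - ca_b, cen_a - ca_b)
    facing = distance <= distance_cutoff and angle_a <= angle_cutoff and angle_b <= angle_cutoff
    return FacingResult(facing=facing, centroid_distance=distance, angle_a=angle_a, angle_b=angle_b)


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

#: Sidechain nitrogen atoms able to carry a positive charge.
BASIC_N_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
#: Sidechain carboxylate oxygens.
ACIDIC_O_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: int
    acidic_residue: int
    basic_name: str
    acidic_name: str
    min_atom_distance: float


def find_salt_bridges(model: StructureModel, cutoff: float = 4.0) -> list[SaltBridge]:
    """All basic-N/acidic-O residue pairs with minimum atom distance <= cutoff.

    Basic residues: Arg (NE, NH1, NH2), Lys (NZ), His (ND1, NE2); acidic:
    Asp (OD1/OD2), Glu (OE1/OE2). Each residue pair is reported once with
    its minimum N–O distance, sorted by residue numbers.
    """
    basic: dict[int, list[int]] = {}
    acidic: dict[int, list[int]] = {}
    for i in range(len(model)):
        rname = str(model.res_names[i]).upper()
        aname = str(model.atom_names[i])
        if rname in BASIC_N_ATOMS and aname in BASIC_N_ATOMS[rname]:
            basic.setdefault(int(model.res_ids[i]), []).append(i)
        if rname in ACIDIC_O_ATOMS and aname in ACIDIC_O_ATOMS[rname]:
            acidic.setdefault(int(model.res_ids[i]), []).append(i)
    bridges = []
    for b_res, b_idx in sorted(basic.items()):
        for a_res, a_idx in sorted(acidic.items()):
            d = np.linalg.norm(
                model.coords[b_idx][:, None, :] - model.coords[a_idx][None, :, :], axis=-1
            )
            dmin = float(d.min())
            if dmin <= cutoff:
                bridges.append(
                    SaltBridge(
                        basic_residue=b_res,
                        acidic_residue=a_res,
                        basic_name=model.residue_name(b_res),
                        acidic_name=model.residue_name(a_res),
                        min_atom_distance=dmin,
                    )
                )
    return bridges
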