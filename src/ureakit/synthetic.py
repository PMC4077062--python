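"""Synthetic data with known ground truth for every downstream stage.

Three generator families:

* labelled alignments with *planted* column-conservation classes, so the
  conservation classifier can be checked against an exact truth table;
* radiotracer uptake datasets drawn from the Michaelis–Menten and
  competitive-inhibition models at the study's assay design (0.5–50 µM
  saturation grid, 1.0 µM tracer, 0.5–3000 µM competition grid, three
  replicates, multiplicative noise bounded so replicate SD stays below
  20% of the mean);
* toy atomic structures with analytically known solvent accessibility,
  planted salt bridges and known cavity-lining residues.

Noise model: each measurement is the model mean times ``(1 + eps)`` with
``eps ~ Normal(0, noise_cv)``, truncated at zero (counts cannot go
negative). Default ``noise_cv = 0.15`` respects the printed <20% SD bound.
All generators take explicit seeds; identical seed and arguments give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import CensoredValue, StructureModel, UptakeDataset
from .conservation import CONSERVATION_CLASSES, LabelledAlignment, classify_column
from .residues import AMINO_ACIDS

__all__ = [
    "PlantedColumn",
    "KineticTruth",
    "gen_msa",
    "gen_saturation",
    "gen_competition",
    "gen_timecourse",
    "gen_toy_structure",
    "ToyStructure",
    "michaelis_menten_rate",
    "competition_rate",
    "DEFAULT_SATURATION_GRID",
    "DEFAULT_COMPETITION_GRID",
    "DEFAULT_TIMEPOINTS",
]

#: Saturation grid spanning the assayed 0.5–50 µM labelled-urea range.
DEFAULT_SATURATION_GRID = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)
#: Competition grid: unlabelled substrate 0.5–3000 µM plus the I=0 anchor.
DEFAULT_COMPETITION_GRID = (0.0, 0.5, 2.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)
#: Time points inside the 2-minute linear uptake window.
DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class PlantedColumn:
    """A reference position with a planted conservation class."""

    ref_position: int  # 1-based
    true_class: str

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ValueError("ref_position is 1-based and must be >= 1")
        if self.true_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"true_class must be one of {CONSERVATION_CLASSES}, got {self.true_class!r}"
            )


@dataclass(frozen=True)
class KineticTruth:
    """Generating parameters of a simulated uptake assay.

    Km (µM), Vmax (pmol·min⁻¹ per 10⁷ conidiospores, or any linear count
    scale), per-substrate Ki (µM; may be censored), tracer concentration L
    (µM), noise CV and seed.
    """

    Km: float
    Vmax: float
    Ki_map: Mapping[str, float | CensoredValue] = field(default_factory=dict)
    L: float = 1.0
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.Km > 0:
            raise ValueError("Km must be > 0")
        if self.Vmax < 0:
            raise ValueError("Vmax must be >= 0")
        if not self.L > 0:
            raise ValueError("tracer concentration L must be > 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        for name, ki in self.Ki_map.items():
            bound = ki.bound if isinstance(ki, CensoredValue) else ki
            if not bound > 0:
                raise ValueError(f"Ki for {name!r} must be > 0")

    def with_seed(self, seed: int) -> "KineticTruth":
        return replace(self, seed=int(seed))


def michaelis_menten_rate(S: np.ndarray | float, Km: float, Vmax: float) -> np.ndarray | float:
    """v = Vmax·S/(Km+S)."""
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def competition_rate(
    I: np.ndarray | float, Km: float, Vmax: float, L: float, Ki: float
) -> np.ndarray | float:
    """Competitive inhibition: v(I) = Vmax·L / (Km·(1+I/Ki) + L)."""
    I = np.asarray(I, dtype=float)
    return Vmax * L / (Km * (1.0 + I / Ki) + L)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, exclude: str = "") -> str:
    pool = [a for a in AMINO_ACIDS if a not in exclude]
    return pool[rng.integers(len(pool))]


def gen_msa(
    n_orth: int,
    n_para: int,
    length: int,
    planted: Sequence[PlantedColumn],
    seed: int,
) -> tuple[LabelledAlignment, pd.DataFrame]:
    """Generate a labelled alignment with planted conservation classes.

    Unplanted columns are filled randomly but redrawn whenever they would
    classify as ``family_conserved`` or ``orthologue_specific`` under the
    default identity rules, so the candidate selectors recover *exactly* the
    planted sets. The reference is ungapped (alignment column == reference
    position). Returns the alignment and a truth table (ref_position,
    true_class).
    """
    if n_orth < 1 or n_para < 1:
        raise ValueError("need at least one orthologue and one paralogue")
    positions = [p.ref_position for p in planted]
    if len(set(positions)) != len(positions):
        raise ValueError("planted positions must be unique")
    too_far = [p.ref_position for p in planted if p.ref_position > length]
    if too_far:
        raise ValueError(
            f"planted positions {too_far} exceed the alignment length {length}"
        )
    for p in planted:
        if p.true_class == "unconserved" and n_orth < 2:
            raise ValueError(
                "planting an unconserved column needs >=2 orthologues (with one "
                "orthologue every column is family/orthologue/reference-specific)"
            )

    rng = np.random.default_rng(seed)
    n_seq = 1 + n_orth + n_para
    cols: list[list[str]] = []
    planted_by_pos = {p.ref_position: p.true_class for p in planted}

    for pos in range(1, length + 1):
        cls = planted_by_pos.get(pos)
        if cls == "family_conserved":
            r = _draw(rng)
            col = [r] * n_seq
        elif cls == "orthologue_specific":
            r = _draw(rng)
            col = [r] * (1 + n_orth) + [_draw(rng, exclude=r) for _ in range(n_para)]
        elif cls == "reference_specific":
            r = _draw(rng)
            col = [r] + [_draw(rng, exclude=r) for _ in range(n_orth)]
            col += [_draw(rng) for _ in range(n_para)]
        elif cls == "unconserved":
            r = _draw(rng)
            col = [r, r, _draw(rng, exclude=r)]
            col += [_draw(rng) for _ in range(n_orth - 2)]
            col += [_draw(rng) for _ in range(n_para)]
        else:  # background column: never family- or orthologue-conserved
            for _ in range(1000):
                col = [_draw(rng) for _ in range(n_seq)]
                bg_cls = classify_column(col[0], col[1 : 1 + n_orth], col[1 + n_orth :])
                if bg_cls not in ("family_conserved", "orthologue_specific"):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a background column")
        cols.append(col)

    matrix = list(zip(*cols))
    ids = ["REF"] + [f"ORTH{i+1}" for i in range(n_orth)] + [f"PARA{i+1}" for i in range(n_para)]
    groups = {"REF": "reference"}
    groups.update({f"ORTH{i+1}": "orthologue" for i in range(n_orth)})
    groups.update({f"PARA{i+1}": "paralogue" for i in range(n_para)})
    aln = LabelledAlignment(
        ids=tuple(ids),
        sequences=tuple("".join(row) for row in matrix),
        groups=groups,
    )
    truth = pd.DataFrame(
        sorted(planted_by_pos.items()), columns=["ref_position", "true_class"]
    )
    return aln, truth


# ---------------------------------------------------------------------------
# uptake datasets
# ---------------------------------------------------------------------------


def _noisy(rng: np.random.Generator, mean: np.ndarray, noise_cv: float) -> np.ndarray:
    if noise_cv == 0:
        return mean.copy()
    eps = rng.normal(0.0, noise_cv, size=mean.shape)
    return np.maximum(mean * (1.0 + eps), 0.0)


def gen_saturation(
    truth: KineticTruth,
    conc_grid: Sequence[float] | None = None,
    reps: int = 3,
    condition: str = "urea",
) -> UptakeDataset:
    """Simulate a saturation series v(S) = Vmax·S/(Km+S) with replicate noise."""
    grid = np.asarray(DEFAULT_SATURATION_GRID if conc_grid is None else conc_grid, float)
    if grid.size == 0:
        raise ValueError("concentration grid is empty")
    if np.any(grid <= 0):
        raise ValueError("saturation concentrations must be strictly positive")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for rep in range(1, reps + 1):
        mean = michaelis_menten_rate(grid, truth.Km, truth.Vmax)
        rows.append(
            pd.DataFrame(
                {"x": grid, "replicate": rep, "signal": _noisy(rng, np.asarray(mean), truth.noise_cv)}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    return UptakeDataset(kind="saturation", condition=condition, data=data)


def gen_competition(
    truth: KineticTruth,
    substrate: str,
    inhibitor_grid: Sequence[float] | None = None,
    reps: int = 3,
) -> UptakeDataset:
    """Simulate tracer uptake against increasing unlabelled competitor.

    Mean follows v(I) = Vmax·L/(Km·(1+I/Ki) + L); at I=0 this is the
    uninhibited rate Vmax·L/(Km+L).
    """
    if substrate not in truth.Ki_map:
        raise KeyError(f"no Ki for substrate {substrate!r} in truth")
    ki = truth.Ki_map[substrate]
    if isinstance(ki, CensoredValue):
        raise ValueError(
            f"Ki for {substrate!r} is censored ({ki}); a bounded-only parameter cannot be simulated"
        )
    grid = np.asarray(DEFAULT_COMPETITION_GRID if inhibitor_grid is None else inhibitor_grid, float)
    if grid.size == 0:
        raise ValueError("inhibitor grid is empty")
    if np.any(grid < 0):
        raise ValueError("inhibitor concentrations must be non-negative")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for rep in range(1, reps + 1):
        mean = competition_rate(grid, truth.Km, truth.Vmax, truth.L, ki)
        rows.append(
            pd.DataFrame(
                {"x": grid, "replicate": rep, "signal": _noisy(rng, np.asarray(mean), truth.noise_cv)}
            )
        )
    data = pd.concat(rows, ignore_index=True)
    return UptakeDataset(
        kind="competition", condition=substrate, data=data, tracer_conc=truth.L
    )


def gen_timecourse(
    truth: KineticTruth,
    S: float = 1.0,
    timepoints: Sequence[float] | None = None,
    plateau_time: float = 2.0,
    reps: int = 3,
    background_rate: float = 0.0,
    condition: str = "uptake",
) -> UptakeDataset:
    """Simulate accumulated tracer signal over time.

    Accumulation is linear with slope v = Vmax·S/(Km+S) + background_rate up
    to ``plateau_time`` (the window where initial velocity is measured),
    then approaches a plateau exponentially with time constant equal to
    ``plateau_time``. ``background_rate`` models carrier-independent uptake
    (the deletion-strain background that is later subtracted).
    """
    t = np.asarray(DEFAULT_TIMEPOINTS if timepoints is None else timepoints, float)
    if np.any(t < 0):
        raise ValueError("time points must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time points must be sorted")
    if np.sum(t <= plateau_time) < 3:
        raise ValueError("need >=3 time points inside the linear window")
    v = float(michaelis_menten_rate(S, truth.Km, truth.Vmax)) + background_rate
    tau = plateau_time
    mean = np.where(
        t <= plateau_time,
        v * t,
        v * plateau_time + v * tau * (1.0 - np.exp(-(t - plateau_time) / tau)),
    )
    rng = np.random.default_rng(truth.seed)
    rows = []
    for rep in range(1, reps + 1):
        rows.append(
            pd.DataFrame({"x": t, "replicate": rep, "signal": _noisy(rng, mean, truth.noise_cv)})
        )
    data = pd.concat(rows, ignore_index=True)
    return UptakeDataset(kind="timecourse", condition=condition, data=data, tracer_conc=S)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


class ToyStructure(NamedTuple):
    """A toy structure plus its documented analytic ground truth."""

    model: StructureModel
    truth: dict


_TOY_KINDS = (
    "single_sphere",
    "disjoint_pair",
    "buried_atom",
    "helix_bundle_with_cavity",
    "planted_salt_bridge",
)

_CARBON_VDW = 1.70


def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    return v / np.linalg.norm(v[0])


def gen_toy_structure(kind: str, probe_radius: float = 2.0) -> ToyStructure:
    """Build a toy structure of the requested ``kind`` with known truth.

    Kinds: ``single_sphere`` (one carbon, exact analytic SASA),
    ``disjoint_pair`` (two far-apart carbons, additive SASA),
    ``buried_atom`` (a carbon fully enclosed by an icosahedral shell, SASA 0),
    ``helix_bundle_with_cavity`` (a ring bundle with inward cavity-lining,
    outward surface and one buried residue; truth lists shipped alongside),
    ``planted_salt_bridge`` (guanidinium-like N 3.0 Å from carboxylate-like O).
    """
    if kind not in _TOY_KINDS:
        raise ValueError(f"unknown toy structure kind {kind!r}; choose from {_TOY_KINDS}")

    if kind == "single_sphere":
        model = StructureModel([1], ["GLY"], ["CA"], ["C"], np.zeros((1, 3)))
        area = 4.0 * np.pi * (_CARBON_VDW + probe_radius) ** 2
        return ToyStructure(model, {"vdw_radius": _CARBON_VDW, "exact_sasa": {1: area}})

    if kind == "disjoint_pair":
        coords = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        model = StructureModel([1, 2], ["GLY", "GLY"], ["CA", "CA"], ["C", "C"], coords)
        area = 4.0 * np.pi * (_CARBON_VDW + probe_radius) ** 2
        return ToyStructure(
            model, {"vdw_radius": _CARBON_VDW, "exact_sasa": {1: area, 2: area}}
        )

    if kind == "buried_atom":
        shell = _icosahedron_vertices() * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        n = len(coords)
        model = StructureModel(
            list(range(1, n + 1)), ["GLY"] * n, ["CA"] * n, ["C"] * n, coords
        )
        return ToyStructure(model, {"buried_residue": 1, "exact_sasa": {1: 0.0}})

    if kind == "planted_salt_bridge":
        # Arg-like sidechain nitrogen 3.0 Å from a Glu-like carboxylate oxygen.
        res_ids = [10, 10, 20, 20]
        res_names = ["ARG", "ARG", "GLU", "GLU"]
        atom_names = ["CA", "NH1", "CA", "OE1"]
        elements = ["C", "N", "C", "O"]
        coords = np.array(
            [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [11.0, 0.0, 0.0], [7.0, 0.0, 0.0]]
        )
        model = StructureModel(res_ids, res_names, atom_names, elements, coords)
        return ToyStructure(
            model, {"bridge": (10, 20), "distance": 3.0}
        )

    # helix_bundle_with_cavity
    n_helix, per_helix = 6, 4
    ring_radius, rise = 9.0, 3.0
    res_ids: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    cavity_lining: list[int] = []
    surface: list[int] = []
    inward_names = ["SER", "THR", "ASN", "TYR", "VAL", "GLN"]
    outward_names = ["LEU", "ALA", "PHE", "VAL"]
    rid = 0
    for h in range(n_helix):
        theta = 2.0 * np.pi * h / n_helix
        ux, uy = np.cos(theta), np.sin(theta)
        for k in range(per_helix):
            rid += 1
            z = rise * k
            inward = k == 1  # one cavity-lining residue per helix, mid-height
            name = inward_names[h] if inward else outward_names[k % len(outward_names)]
            cb_r = ring_radius - 2.0 if inward else ring_radius + 2.0
            res_ids += [rid, rid]
            res_names += [name, name]
            atom_names += ["CA", "CB"]
            elements += ["C", "C"]
            coords += [[ring_radius * ux, ring_radius * uy, z], [cb_r * ux, cb_r * uy, z]]
            (cavity_lining if inward else surface).append(rid)
    # one buried residue: its CB enclosed by an icosahedral shell of dummies
    rid += 1
    buried_id = rid
    cb = np.array([0.0, 0.0, -12.0])
    ca = cb + np.array([-1.5, 0.0, 0.0])
    res_ids += [rid, rid]
    res_names += ["SER", "SER"]
    atom_names += ["CA", "CB"]
    elements += ["C", "C"]
    coords += [ca.tolist(), cb.tolist()]
    for vert in _icosahedron_vertices() * 2.0:
        rid += 1
        res_ids.append(rid)
        res_names.append("GLY")
        atom_names.append("CA")
        elements.append("C")
        coords.append((cb + vert).tolist())
    model = StructureModel(res_ids, res_names, atom_names, elements, np.asarray(coords))
    truth = {
        "cavity_lining": cavity_lining,
        "surface": surface,
        "buried": [buried_id],
        "polar_cavity": [
            r for r, name in zip(cavity_lining, inward_names) if name != "VAL"
        ],
    }
    return ToyStructure(model, truth)
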