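"""Independent oracles used by the tests.

Each oracle recomputes a quantity by a route independent of the package
implementation: latitude-longitude quadrature for solvent accessible
areas, plain nested-loop scans for salt bridges, and grid / profile
searches for the curve fits.
"""

from __future__ import annotations

import numpy as np

from ureakit.containers import StructureModel
from ureakit.residues import VDW_RADII
from ureakit.structure import ACIDIC_O_ATOMS, BASIC_N_ATOMS


def sasa_quadrature(
    model: StructureModel, probe_radius: float = 2.0, n_theta: int = 180
) -> np.ndarray:
    """Per-atom SASA by dense latitude-longitude quadrature (independent of
    the golden-spiral point set used by the implementation)."""
    radii = np.array([VDW_RADII[str(e).upper()] for e in model.elements]) + probe_radius
    coords = model.coords
    out = np.empty(len(model))
    theta_edges = np.linspace(0.0, np.pi, n_theta + 1)
    theta_mid = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    d_theta = np.diff(theta_edges)
    for i in range(len(model)):
        R = radii[i]
        area = 0.0
        for theta, dth in zip(theta_mid, d_theta):
            n_phi = max(int(round(2 * n_theta * np.sin(theta))), 1)
            phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
            pts = coords[i] + R * np.column_stack(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.full(n_phi, np.cos(theta)),
                ]
            )
            free = np.ones(n_phi, dtype=bool)
            for j in range(len(model)):
                if j == i:
                    continue
                d2 = np.sum((pts - coords[j]) ** 2, axis=1)
                free &= d2 > radii[j] ** 2
            # cell area = R^2 * sin(theta) * dtheta * dphi
            area += free.sum() * R**2 * np.sin(theta) * dth * (2.0 * np.pi / n_phi)
        out[i] = area
    return out


def brute_force_salt_bridges(model: StructureModel, cutoff: float = 4.0) -> set[tuple[int, int]]:
    """All (basic_res, acidic_res) pairs with any qualifying N-O atom pair
    within the cutoff, found by a plain double loop over atoms."""
    found: dict[tuple[int, int], float] = {}
    for i in range(len(model)):
        rn_i = str(model.res_names[i]).upper()
        an_i = str(model.atom_names[i])
        if rn_i not in BASIC_N_ATOMS or an_i not in BASIC_N_ATOMS[rn_i]:
            continue
        for j in range(len(model)):
            rn_j = str(model.res_names[j]).upper()
            an_j = str(model.atom_names[j])
            if rn_j not in ACIDIC_O_ATOMS or an_j not in ACIDIC_O_ATOMS[rn_j]:
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            key = (int(model.res_ids[i]), int(model.res_ids[j]))
            if d <= cutoff and d < found.get(key, np.inf):
                found[key] = d
    return set(found)


def grid_search_michaelis_menten(
    S: np.ndarray,
    v: np.ndarray,
    km_grid: np.ndarray,
    vmax_grid: np.ndarray,
    relative: bool = True,
) -> tuple[float, float]:
    """Exhaustive lattice search minimising the (optionally relative) SSE."""
    best = (np.inf, np.nan, np.nan)
    for km in km_grid:
        for vmax in vmax_grid:
            pred = vmax * S / (km + S)
            resid = v - pred
            if relative:
                resid = resid / np.maximum(np.abs(v), 1e-12)
            sse = float(np.sum(resid**2))
            if sse < best[0]:
                best = (sse, float(km), float(vmax))
    return best[1], best[2]


def profile_ic50(
    I: np.ndarray, v: np.ndarray, ic50_grid: np.ndarray
) -> float:
    """Profile search over IC50 with the optimal V0 solved in closed form.

    For fixed IC50 the model v = V0 * g(I) is linear in V0, so the
    least-squares V0 is <v, g>/<g, g>.
    """
    best = (np.inf, np.nan)
    for ic50 in ic50_grid:
        g = 1.0 / (1.0 + I / ic50)
        v0 = float(np.dot(v, g) / np.dot(g, g))
        sse = float(np.sum((v - v0 * g) ** 2))
        if sse < best[0]:
            best = (sse, float(ic50))
    return best[1]
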