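"""Rule-based phenotype classification of transporter mutants.

Combines the background-subtracted relative uptake rate (V%), the kinetic
constants (possibly censored), and the subcellular localization category
(membrane vs ER retention) into one of six discrete phenotype classes. The
decision list fires in a fixed order; exactly one class is assigned and
the fired rules are returned as the rationale.

Growth-plate scores (+++, ++-, ...) are ordinal wet-lab observations; they
are carried through for reporting but never used in classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CensoredValue, parse_maybe_censored

__all__ = [
    "PHENOTYPE_CLASSES",
    "MutantRecord",
    "PhenotypeClass",
    "classify_mutant",
    "records_from_table",
    "classify_table",
]

PHENOTYPE_CLASSES = (
    "wt_like",
    "transport_null_membrane",
    "trafficking_defective",
    "partial_transport",
    "selectivity_altered",
    "truncation_null",
)

LOCALIZATIONS = ("M", "ER", "n.d.")


@dataclass(frozen=True)
class MutantRecord:
    """One allele's measured phenotype inputs.

    ``V_percent`` may be censored (``"<2"``); ``Km`` and each ``Ki`` may be
    censored (``">3000"``) or absent (None) when not measurable.
    """

    allele: str
    localization: str = "n.d."
    V_percent: float | CensoredValue | None = None
    Km: float | CensoredValue | None = None
    Ki: Mapping[str, float | CensoredValue] = field(default_factory=dict)
    location: str | None = None
    growth_urea: str | None = None
    growth_thiourea: str | None = None
    is_truncation: bool = False

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"localization must be one of {LOCALIZATIONS}")
        v = self.V_percent
        if isinstance(v, (int, float)) and v < 0:
            raise ValueError("V_percent must be >= 0")


@dataclass(frozen=True)
class PhenotypeClass:
    """An assigned phenotype class with the rules that fired."""

    label: str
    rationale: tuple[str, ...]
    needs_review: bool = False

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class {self.label!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


def _v_value(v: float | CensoredValue | None) -> float | None:
    if v is None:
        return None
    if isinstance(v, CensoredValue):
        # "<2" compared at its bound: at or below the loss-of-function limit
        return v.bound if v.op == "<" else v.bound
    return float(v)


def _effective(value: float | CensoredValue) -> float:
    return value.bound if isinstance(value, CensoredValue) else float(value)


def fold_change(a: float | CensoredValue, b: float | CensoredValue) -> float:
    """Symmetric fold change; censored constants are compared at their bounds.

    Two constants censored on the same side count as unshifted when their
    bounds are equal; otherwise the bounds enter the ratio.
    """
    if isinstance(a, CensoredValue) and isinstance(b, CensoredValue) and a.op == b.op:
        if a.bound == b.bound:
            return 1.0
    x, y = _effective(a), _effective(b)
    if x <= 0 or y <= 0:
        raise ValueError("kinetic constants must be positive")
    return max(x / y, y / x)


def classify_mutant(
    rec: MutantRecord,
    wt_ref: MutantRecord,
    fold_threshold: float = 1.5,
    v_null: float = 2.0,
    v_wt_like: float = 90.0,
) -> PhenotypeClass:
    """Assign one phenotype class by a first-match-wins decision list.

    1. ER localization → ``trafficking_defective``.
    2. V% ≤ ``v_null`` with membrane localization → ``transport_null_membrane``.
    3. Premature-stop allele → ``truncation_null``.
    4. V% ≥ ``v_wt_like`` and every shared kinetic constant within
       ``fold_threshold``-fold of wild type → ``wt_like``.
    5. Any constant shifted ≥ ``fold_threshold``-fold with V% > ``v_null``
       → ``selectivity_altered``.
    6. Otherwise → ``partial_transport``.

    A record with V% ≤ v_null but missing localization (and no premature
    stop) cannot be placed confidently; it is classified on V% alone and
    flagged ``needs_review``.
    """
    if isinstance(wt_ref.Km, CensoredValue) or wt_ref.Km is None:
        raise ValueError("wild-type reference needs an uncensored Km")
    wt_v = _v_value(wt_ref.V_percent)
    if wt_v is None or abs(wt_v - 100.0) > 1e-9:
        raise ValueError("wild-type reference must have V% = 100")

    fired: list[str] = []
    v = _v_value(rec.V_percent)
    v_is_null = v is not None and v <= v_null

    if rec.localization == "ER":
        fired.append("localization=ER: retained in the endoplasmic reticulum")
        return PhenotypeClass(label="trafficking_defective", rationale=tuple(fired))
    if v_is_null and rec.localization == "M":
        fired.append(f"V%<={v_null:g} with membrane localization: transport null at the membrane")
        return PhenotypeClass(label="transport_null_membrane", rationale=tuple(fired))
    if rec.is_truncation:
        fired.append("premature stop codon: truncated protein")
        return PhenotypeClass(label="truncation_null", rationale=tuple(fired))
    if v_is_null and rec.localization == "n.d.":
        fired.append(
            f"V%<={v_null:g} but localization not determined: null phenotype of unknown origin"
        )
        return PhenotypeClass(
            label="transport_null_membrane", rationale=tuple(fired), needs_review=True
        )

    # fold changes over the constants shared with the wild-type reference
    shifts: list[str] = []
    pairs: list[tuple[str, float | CensoredValue, float | CensoredValue]] = []
    if rec.Km is not None and wt_ref.Km is not None:
        pairs.append(("Km", rec.Km, wt_ref.Km))
    for substrate, ki in rec.Ki.items():
        wt_ki = wt_ref.Ki.get(substrate)
        if ki is not None and wt_ki is not None:
            pairs.append((f"Ki[{substrate}]", ki, wt_ki))
    for name, a, b in pairs:
        f = fold_change(a, b)
        if f >= fold_threshold:
            shifts.append(f"{name} shifted {f:.2g}-fold vs wt")

    if v is not None and v >= v_wt_like and not shifts:
        fired.append(
            f"V%>={v_wt_like:g} and all constants within {fold_threshold:g}-fold of wt"
        )
        return PhenotypeClass(label="wt_like", rationale=tuple(fired))
    if shifts and (v is None or v > v_null):
        fired.extend(shifts)
        return PhenotypeClass(label="selectivity_altered", rationale=tuple(fired))
    fired.append("reduced transport without qualifying constant shifts")
    return PhenotypeClass(label="partial_transport", rationale=tuple(fired))


# ---------------------------------------------------------------------------
# table-level interface
# ---------------------------------------------------------------------------

_KI_COLUMNS = {
    "2-thiourea": "Ki_thiourea_uM",
    "acetamide": "Ki_acetamide_uM",
    "guanidine": "Ki_guanidine_uM",
}


def _cell(row: pd.Series, col: str) -> float | CensoredValue | None:
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    return parse_maybe_censored(raw)


def records_from_table(table: pd.DataFrame) -> list[MutantRecord]:
    """Build :class:`MutantRecord` objects from an allele table frame.

    Expects the packaged table layout (see ``datasets.load_allele_table``).
    """
    records = []
    for allele, row in table.iterrows():
        loc = row.get("localization")
        loc = str(loc) if isinstance(loc, str) and loc.strip() else "n.d."
        ki = {}
        for substrate, col in _KI_COLUMNS.items():
            val = _cell(row, col)
            if val is not None:
                ki[substrate] = val
        records.append(
            MutantRecord(
                allele=str(allele),
                localization=loc if loc in LOCALIZATIONS else "n.d.",
                V_percent=_cell(row, "V_percent"),
                Km=_cell(row, "Km_uM"),
                Ki=ki,
                location=str(row.get("location")) if isinstance(row.get("location"), str) else None,
                growth_urea=row.get("growth_urea"),
                growth_thiourea=row.get("growth_thiourea"),
                is_truncation="Stop" in str(allele) or str(allele).endswith("*"),
            )
        )
    return records


def classify_table(
    records: Sequence[MutantRecord],
    wt_ref: MutantRecord | None = None,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Classify every record against the wild-type reference.

    Returns a frame indexed by allele with the class label, review flag and
    a semicolon-joined rationale.
    """
    if wt_ref is None:
        matches = [r for r in records if r.allele == "wt"]
        if not matches:
            raise ValueError("no wild-type record found; pass wt_ref explicitly")
        wt_ref = matches[0]
    rows = []
    for rec in records:
        cls = classify_mutant(rec, wt_ref, fold_threshold=fold_threshold)
        rows.append(
            {
                "allele": rec.allele,
                "phenotype_class": cls.label,
                "needs_review": cls.needs_review,
                "rationale": "; ".join(cls.rationale),
            }
        )
    return pd.DataFrame(rows).set_index("allele")
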