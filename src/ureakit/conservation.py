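"""Conservation-contrast scoring of labelled multiple sequence alignments.

The central idea: residues important for transport in a reference
transporter should be conserved across its functionally characterized
orthologues (urea transporters in other species) while *not* conserved in
its within-genome paralogues, whose substrate specificity has diverged.
Columns of a reference/orthologue/paralogue-labelled alignment are
classified into four mutually exclusive classes and the two candidate sets
(orthologue-specific; family-conserved) are read off the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .containers import CandidateResidue
from .residues import AMINO_ACIDS, SIMILARITY_CLASSES

__all__ = [
    "CONSERVATION_CLASSES",
    "GROUPS",
    "LabelledAlignment",
    "ColumnProfile",
    "read_alignment",
    "read_group_map",
    "column_to_ref_map",
    "classify_column",
    "profile_columns",
    "select_directed_candidates",
    "select_family_conserved",
]

CONSERVATION_CLASSES = (
    "family_conserved",
    "orthologue_specific",
    "reference_specific",
    "unconserved",
)
GROUPS = ("reference", "orthologue", "paralogue")
GAP = "-"


class AlignmentError(ValueError):
    """Invalid labelled alignment (ragged, unlabelled or mislabelled)."""


@dataclass(frozen=True)
class LabelledAlignment:
    """Aligned sequences partitioned into reference/orthologue/paralogue groups."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        missing = [i for i in self.ids if i not in self.groups]
        if missing:
            raise AlignmentError(f"no group assigned for ids: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise AlignmentError(f"unknown group labels: {sorted(bad)}")
        refs = [i for i in self.ids if self.groups[i] == "reference"]
        if len(refs) != 1:
            raise AlignmentError(f"exactly one reference sequence required, found {len(refs)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def _ids_in(self, group: str) -> list[str]:
        return [i for i in self.ids if self.groups[i] == group]

    @property
    def reference_id(self) -> str:
        return self._ids_in("reference")[0]

    @property
    def orthologue_ids(self) -> list[str]:
        return self._ids_in("orthologue")

    @property
    def paralogue_ids(self) -> list[str]:
        return self._ids_in("paralogue")

    def sequence(self, seq_id: str) -> str:
        return self.sequences[self.ids.index(seq_id)]

    @property
    def reference_seq(self) -> str:
        return self.sequence(self.reference_id)

    @property
    def reference_ungapped(self) -> str:
        return self.reference_seq.replace(GAP, "")

    def column(self, index: int, group: str) -> list[str]:
        """Residues of one alignment column restricted to a group."""
        return [self.sequence(i)[index] for i in self._ids_in(group)]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, group) into a group map."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"group map rows need two columns, got: {line!r}")
        out[parts[0]] = parts[1]
    return out


def read_alignment(path: str | Path, group_map: Mapping[str, str]) -> LabelledAlignment:
    """Read an aligned FASTA or Clustal file and attach group labels.

    ``group_map`` must cover every sequence id in the file; exactly one id
    must be labelled ``reference`` and at least one ``orthologue``.
    """
    from Bio import AlignIO

    last_err: Exception | None = None
    aln = None
    for fmt in ("fasta", "clustal"):
        try:
            aln = AlignIO.read(str(path), fmt)
            break
        except ValueError as err:
            last_err = err
    if aln is None:
        raise AlignmentError(f"could not parse {path} as aligned FASTA or Clustal: {last_err}")

    ids = tuple(rec.id for rec in aln)
    seqs = tuple(str(rec.seq).upper() for rec in aln)
    unknown = [i for i in ids if i not in group_map]
    if unknown:
        raise AlignmentError(f"group map is missing ids: {unknown}")
    labelled = LabelledAlignment(ids=ids, sequences=seqs, groups=dict(group_map))
    if not labelled.orthologue_ids:
        raise AlignmentError("alignment contains zero orthologue sequences")
    return labelled


def column_to_ref_map(aln: LabelledAlignment) -> dict[int, int | None]:
    """Map 0-based alignment columns to 1-based ungapped reference positions.

    Columns where the reference carries a gap map to ``None``.
    """
    mapping: dict[int, int | None] = {}
    pos = 0
    for col, residue in enumerate(aln.reference_seq):
        if residue == GAP:
            mapping[col] = None
        else:
            pos += 1
            mapping[col] = pos
    return mapping


def _match(a: str, b: str, mode: str) -> bool:
    if a == GAP or b == GAP:
        return False  # gaps never match anything
    if a == b:
        return True
    if mode == "similarity":
        return any(a in cls and b in cls for cls in SIMILARITY_CLASSES)
    return False


def classify_column(
    ref_residue: str,
    orthologue_residues: Sequence[str],
    paralogue_residues: Sequence[str],
    mode: Literal["identity", "similarity"] = "identity",
    paralogue_rule: Literal["not_all", "none"] = "not_all",
) -> str:
    """Classify one alignment column into the four-class conservation scheme.

    Decision table (classes mutually exclusive, first match wins):

    1. ``family_conserved`` — every orthologue *and* every paralogue matches
       the reference residue.
    2. ``orthologue_specific`` — every orthologue matches the reference and
       the paralogue non-conservation predicate holds (default ``not_all``:
       not every paralogue matches; stricter ``none``: no paralogue matches).
    3. ``reference_specific`` — no orthologue matches the reference.
    4. ``unconserved`` — anything else.

    ``mode`` selects strict identity (default) or fixed-physicochemical-class
    similarity matching. Gaps in any group member count as non-matching; a
    gapped reference is not classifiable at reference numbering.
    """
    if ref_residue == GAP:
        raise ValueError("reference gap column is not classifiable at reference numbering")
    orth_match = [_match(ref_residue, r, mode) for r in orthologue_residues]
    para_match = [_match(ref_residue, r, mode) for r in paralogue_residues]
    if orth_match and all(orth_match) and all(para_match):
        return "family_conserved"
    if orth_match and all(orth_match):
        para_nonconserved = (
            not all(para_match) if paralogue_rule == "not_all" else not any(para_match)
        )
        if para_nonconserved:
            return "orthologue_specific"
        return "unconserved"
    if not any(orth_match):
        return "reference_specific"
    return "unconserved"


@dataclass(frozen=True)
class ColumnProfile:
    """One classified alignment column mapped to reference numbering."""

    column_index: int
    ref_position: int | None
    ref_residue: str
    residues_by_group: Mapping[str, tuple[str, ...]]
    conservation_class: str | None


def profile_columns(
    aln: LabelledAlignment,
    mode: Literal["identity", "similarity"] = "identity",
    paralogue_rule: Literal["not_all", "none"] = "not_all",
) -> list[ColumnProfile]:
    """Classify every alignment column; reference-gap columns get class None."""
    ref_map = column_to_ref_map(aln)
    profiles = []
    for col in range(aln.length):
        ref_res = aln.reference_seq[col]
        orth = aln.column(col, "orthologue")
        para = aln.column(col, "paralogue")
        if ref_map[col] is None:
            cls = None
        else:
            cls = classify_column(ref_res, orth, para, mode=mode, paralogue_rule=paralogue_rule)
        profiles.append(
            ColumnProfile(
                column_index=col,
                ref_position=ref_map[col],
                ref_residue=ref_res,
                residues_by_group={
                    "reference": (ref_res,),
                    "orthologue": tuple(orth),
                    "paralogue": tuple(para),
                },
                conservation_class=cls,
            )
        )
    return profiles


def _candidates_of_class(
    aln: LabelledAlignment,
    wanted: str,
    mode: str,
    paralogue_rule: str,
) -> list[CandidateResidue]:
    out = [
        CandidateResidue(
            ref_position=p.ref_position,
            ref_residue=p.ref_residue,
            conservation_class=p.conservation_class,
        )
        for p in profile_columns(aln, mode=mode, paralogue_rule=paralogue_rule)
        if p.conservation_class == wanted
    ]
    return sorted(out, key=lambda c: c.ref_position)


def select_directed_candidates(
    aln: LabelledAlignment,
    mode: Literal["identity", "similarity"] = "identity",
    paralogue_rule: Literal["not_all", "none"] = "not_all",
) -> list[CandidateResidue]:
    """Positions conserved in all orthologues but not in the paralogues.

    The primary mutagenesis-candidate filter: a residue conserved across the
    functionally characterized orthologues yet divergent in the paralogues is
    a strong a-priori candidate for transport function.
    """
    if not aln.orthologue_ids or not aln.paralogue_ids:
        raise AlignmentError("directed-candidate selection needs >=1 orthologue and >=1 paralogue")
    return _candidates_of_class(aln, "orthologue_specific", mode, paralogue_rule)


def select_family_conserved(
    aln: LabelledAlignment,
    scope: Literal["orthologues_only", "all"] = "all",
    mode: Literal["identity", "similarity"] = "identity",
) -> list[CandidateResidue]:
    """Positions conserved across the whole family (under the chosen scope).

    ``scope="all"`` requires identity across orthologues and paralogues;
    ``scope="orthologues_only"`` restricts the family to the reference plus
    its orthologues (the urea-transporter family proper).
    """
    if scope == "all":
        return _candidates_of_class(aln, "family_conserved", mode, "not_all")
    # orthologues_only: a column counts as family-conserved when the
    # reference and every orthologue match, paralogues disregarded.
    ref_map = column_to_ref_map(aln)
    out = []
    for col in range(aln.length):
        pos = ref_map[col]
        if pos is None:
            continue
        ref_res = aln.reference_seq[col]
        if all(_match(ref_res, r, mode) for r in aln.column(col, "orthologue")):
            out.append(
                CandidateResidue(
                    ref_position=pos, ref_residue=ref_res, conservation_class="family_conserved"
                )
            )
    return sorted(out, key=lambda c: c.ref_position)
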