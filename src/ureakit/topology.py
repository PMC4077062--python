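"""Membrane-topology annotation of reference residue positions.

Topology is consumed as an annotation table (label, start, end,
compartment), never predicted. Segment ranges are inclusive on both ends
and 1-based, matching the field's residue naming (Y106, S446, ...). The
package ships a 15-TMS urea-transporter fixture whose segment memberships
match the published per-residue locations; the exact boundary integers are
a repository choice since no numeric boundaries are published.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .containers import CandidateResidue

__all__ = [
    "TopologySegment",
    "TopologyAnnotation",
    "read_topology",
    "load_urea_topology",
    "locate_residue",
    "annotate_candidates",
]

COMPARTMENTS = ("membrane", "intracellular", "extracellular")


@dataclass(frozen=True)
class TopologySegment:
    label: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    compartment: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label}: inverted range {self.start}..{self.end}")
        if self.start < 1:
            raise ValueError(f"segment {self.label}: start must be >= 1")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"segment {self.label}: compartment must be one of {COMPARTMENTS}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, non-overlapping membrane-topology segments."""

    segments: tuple[TopologySegment, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.segments, key=lambda s: s.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlapping segments: {prev.label} ({prev.start}..{prev.end}) and "
                    f"{nxt.label} ({nxt.start}..{nxt.end})"
                )
        object.__setattr__(self, "segments", tuple(ordered))


def read_topology(path: str | Path) -> TopologyAnnotation:
    """Read a topology TSV with columns label, start, end, compartment."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "start", "end", "compartment"}
    if not required.issubset(df.columns):
        raise ValueError(f"topology TSV needs columns {sorted(required)}")
    segments = [
        TopologySegment(
            label=str(row.label),
            start=int(row.start),
            end=int(row.end),
            compartment=str(row.compartment),
        )
        for row in df.itertuples()
    ]
    return TopologyAnnotation(segments=tuple(segments))


def load_urea_topology() -> TopologyAnnotation:
    """The packaged 15-TMS urea-transporter topology fixture."""
    ref = resources.files("ureakit.data").joinpath("urea_topology.tsv")
    with resources.as_file(ref) as path:
        return read_topology(path)


def locate_residue(topo: TopologyAnnotation, ref_position: int) -> str:
    """Label of the unique segment containing ``ref_position``, else ``"unannotated"``."""
    if ref_position < 1:
        raise ValueError("positions are 1-based")
    for seg in topo.segments:
        if ref_position in seg:
            return seg.label
    return "unannotated"


def annotate_candidates(
    topo: TopologyAnnotation, candidates: Sequence[CandidateResidue]
) -> list[CandidateResidue]:
    """Attach a topology label to each candidate (count preserved)."""
    return [
        CandidateResidue(
            ref_position=c.ref_position,
            ref_residue=c.ref_residue,
            conservation_class=c.conservation_class,
            topology_label=locate_residue(topo, c.ref_position),
            exposed=c.exposed,
            polar=c.polar,
        )
        for c in candidates
    ]
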