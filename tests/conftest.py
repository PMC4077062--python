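import numpy as np
import pytest

from ureakit.conservation import LabelledAlignment
from ureakit.containers import StructureModel


@pytest.fixture
def nine_seq_alignment() -> LabelledAlignment:
    """A small hand-built alignment: 1 reference, 5 orthologues, 3 paralogues.

    Column classes by construction (0-based columns):
      0: family-conserved G; 1: orthologue-specific Y (paralogues diverge);
      2: unconserved (orthologues split); 3: reference-specific W;
      4: reference gap in one orthologue (gap treated as mismatch).
    """
    seqs = {
        "REF":   "GYAWT",
        "ORTH1": "GYAST",
        "ORTH2": "GYAST",
        "ORTH3": "GYSST",
        "ORTH4": "GYSST",
        "ORTH5": "GY-ST",
        "PARA1": "GFAAT",
        "PARA2": "GLAAT",
        "PARA3": "GSAAT",
    }
    groups = {"REF": "reference"}
    groups.update({f"ORTH{i}": "orthologue" for i in range(1, 6)})
    groups.update({f"PARA{i}": "paralogue" for i in range(1, 4)})
    return LabelledAlignment(
        ids=tuple(seqs), sequences=tuple(seqs.values()), groups=groups
    )


@pytest.fixture
def facing_pair_model() -> StructureModel:
    """Two tyrosine-like sidechains pointing at each other, centroids 6 Å apart."""
    res_ids = [1, 1, 2, 2]
    res_names = ["TYR", "TYR", "TYR", "TYR"]
    atom_names = ["CA", "CB", "CA", "CB"]
    elements = ["C", "C", "C", "C"]
    coords = np.array(
        [[-5.0, 0.0, 0.0], [-3.0, 0.0, 0.0], [5.0, 0.0, 0.0], [3.0, 0.0, 0.0]]
    )
    return StructureModel(res_ids, res_names, atom_names, elements, coords)


@pytest.fixture
def averted_pair_model() -> StructureModel:
    """The same pair with sidechains rotated to point away from each other."""
    res_ids = [1, 1, 2, 2]
    res_names = ["TYR", "TYR", "TYR", "TYR"]
    atom_names = ["CA", "CB", "CA", "CB"]
    elements = ["C", "C", "C", "C"]
    coords = np.array(
        [[-5.0, 0.0, 0.0], [-7.0, 0.0, 0.0], [5.0, 0.0, 0.0], [7.0, 0.0, 0.0]]
    )
    return StructureModel(res_ids, res_names, atom_names, elements, coords)
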