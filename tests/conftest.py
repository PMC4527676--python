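import numpy as np
import pytest
from hypothesis import settings

from globinsp.io_formats import CoordinateTrace, TraceResidue

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def pdb_atom_line(serial, resname, chain, resseq, x, y, z,
                  occupancy=1.0, altloc=" ", icode=" ", name=" CA ",
                  record="ATOM"):
    """One fixed-column PDB ATOM/HETATM line."""
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {name.strip()[0]:>2s}"
    )


def make_trace(coords, structure_id="s", chain_id="A", sequence=None):
    coords = np.asarray(coords, dtype=float)
    seq = sequence or "A" * len(coords)
    residues = [
        TraceResidue(i + 1, None, seq[i], coords[i]) for i in range(len(coords))
    ]
    return CoordinateTrace(structure_id, chain_id, residues)


@pytest.fixture(scope="session")
def mb_reference():
    from globinsp.globin_fold import default_reference

    return default_reference()


@pytest.fixture(scope="session")
def bundle_template():
    from globinsp.synthetic_data import make_helical_template

    return make_helical_template(8, 19)
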