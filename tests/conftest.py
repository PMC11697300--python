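import pytest

from gaingrn.gaindetect import detect_gain
from gaingrn.synthgain import (build_domain, make_registry_for_spec,
                               preset_canonical, preset_minimal_a)


@pytest.fixture(scope="session")
def canonical_spec():
    return preset_canonical()


@pytest.fixture(scope="session")
def canonical_domain(canonical_spec):
    return build_domain(canonical_spec, seed=1)


@pytest.fixture(scope="session")
def canonical_registry(canonical_spec):
    return make_registry_for_spec(canonical_spec, group="canonical")


@pytest.fixture(scope="session")
def minimal_a_spec():
    return preset_minimal_a()


@pytest.fixture(scope="session")
def detected_canonical(canonical_domain):
    dom = detect_gain(canonical_domain.structure, canonical_domain.sse_truth,
                      group="canonical")
    assert dom.valid
    return dom


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.011  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.022  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.033  1.00  0.00           O
ATOM      9  N   SER A   3       6.213   3.820   0.020  1.00  0.00           N
ATOM     10  CA  SER A   3       7.671   3.812   0.031  1.00  0.00           C
ATOM     11  C   SER A   3       8.214   5.235   0.042  1.00  0.00           C
ATOM     12  O   SER A   3       7.453   6.205   0.053  1.00  0.00           O
END
"""

# one altloc pair on the CA of residue 2 (occupancies 0.6 at x=4.0, 0.4 at x=9.9)
ALTLOC_CIF = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1  N N  . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A
ATOM 2  C CA . ALA A 1 1 ? 1.458 0.000 0.000 1.00 0.00 1 A
ATOM 3  C C  . ALA A 1 1 ? 2.009 1.420 0.000 1.00 0.00 1 A
ATOM 4  N N  . GLY A 1 2 ? 3.332 1.536 0.000 1.00 0.00 2 A
ATOM 5  C CA A GLY A 1 2 ? 4.000 2.800 0.000 0.60 0.00 2 A
ATOM 6  C CA B GLY A 1 2 ? 9.900 2.800 0.000 0.40 0.00 2 A
ATOM 7  C C  . GLY A 1 2 ? 5.504 2.693 0.022 1.00 0.00 2 A
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def altloc_cif(tmp_path):
    p = tmp_path / "altloc.cif"
    p.write_text(ALTLOC_CIF)
    return p
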