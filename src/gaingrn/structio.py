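"""Structure and secondary-structure I/O.

Reads single-chain protein structures (PDB/mmCIF via gemmi) into a light
residue-level data model, parses STRIDE and DSSP assignment files, and
provides a dihedral-window fallback assigner for when neither is available.
Secondary structure is always collapsed to three classes: H (helix, incl.
3_10 and pi), E (strand/bridge) and C (everything else) — the detection
signal downstream is binary helix/strand, so finer classes carry no
information for it.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: collapse of 7/8-class STRIDE/DSSP codes to {H, E, C}
SSE_COLLAPSE = {
    "G": "H", "H": "H", "I": "H",
    "E": "E", "B": "E", "b": "E",
}


@dataclass
class Residue:
    """One amino-acid residue with its heavy atoms.

    ``ordinal`` is the 1-based position within the chain as read; the
    ``author_number`` is whatever the source file called the residue and is
    retained only for output and mutation-table reconciliation.
    """

    ordinal: int
    author_number: int
    aa1: str
    heavy_atoms: list  # list of (atom_name, np.ndarray shape (3,))
    ca: Optional[np.ndarray] = None

    @property
    def is_complete(self) -> bool:
        return self.ca is not None

    def atom(self, name: str) -> Optional[np.ndarray]:
        for n, xyz in self.heavy_atoms:
            if n == name:
                return xyz
        return None

    def heavy_coords(self) -> np.ndarray:
        if not self.heavy_atoms:
            return np.zeros((0, 3))
        return np.vstack([xyz for _, xyz in self.heavy_atoms])


@dataclass
class Structure:
    """A single-chain structure: an ordered list of residues."""

    id: str
    chain: str
    residues: list = field(default_factory=list)
    provenance: str = "memory"

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, ordinal: int) -> Residue:
        """Access by 1-based ordinal."""
        return self.residues[ordinal - 1]

    @property
    def sequence(self) -> str:
        return "".join(r.aa1 for r in self.residues)

    def ca_coords(self, ordinals: Optional[Sequence[int]] = None) -> np.ndarray:
        """Cα coordinates (n, 3); residues lacking Cα are excluded.

        When ``ordinals`` is given, only those with a Cα are returned, in
        the given order.
        """
        if ordinals is None:
            ordinals = [r.ordinal for r in self.residues]
        coords = [self[o].ca for o in ordinals if self[o].ca is not None]
        if not coords:
            return np.zeros((0, 3))
        return np.vstack(coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy (x -> R x + t)."""
        res = []
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for r in self.residues:
            atoms = [(n, R @ xyz + t) for n, xyz in r.heavy_atoms]
            ca = R @ r.ca + t if r.ca is not None else None
            res.append(Residue(r.ordinal, r.author_number, r.aa1, atoms, ca))
        return Structure(self.id, self.chain, res, self.provenance)


@dataclass
class SSEAssignment:
    """Per-residue 3-class secondary structure, parallel to a Structure."""

    classes: str  # one of H/E/C per residue
    source: str   # stride-file | dssp-file | builtin | truth

    def __post_init__(self) -> None:
        bad = set(self.classes) - {"H", "E", "C"}
        if bad:
            raise ValueError(f"illegal SSE classes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, ordinal: int) -> str:
        return self.classes[ordinal - 1]


def _pick_altloc(atoms: Iterable[gemmi.Atom]):
    """Keep a single conformer per atom name, the highest-occupancy one."""
    best = {}
    for a in atoms:
        if a.is_hydrogen():
            continue
        prev = best.get(a.name)
        if prev is None or a.occ > prev.occ:
            best[a.name] = a
    return best.values()


def read_structure(path: str | os.PathLike, chain: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a single-chain :class:`Structure`.

    Only the first model of multi-model files is used; waters, ligands and
    hydrogens are dropped; alternate locations are resolved to the
    highest-occupancy conformer. Residue ordinals are assigned 1..n in file
    order.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(path)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ValueError(f"{path}: multiple chains {names}, specify one")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} absent (have {names})")
    gchain = model[chain]

    residues: list[Residue] = []
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and info.is_water():
            continue
        if info is not None and info.is_amino_acid():
            aa1 = info.one_letter_code.upper()
        elif res.name in AA3_TO_1:
            aa1 = AA3_TO_1[res.name]
        else:
            continue  # ligand / nucleic / unknown het
        atoms = []
        ca = None
        for a in _pick_altloc(res):
            xyz = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
            atoms.append((a.name, xyz))
            if a.name == "CA":
                ca = xyz
        residues.append(
            Residue(len(residues) + 1, res.seqid.num, aa1, atoms, ca)
        )
    if not residues:
        raise ValueError(f"{path}: chain {chain} has no amino-acid residues")
    if all(r.ca is None for r in residues):
        raise ValueError(f"{path}: chain {chain} has no residues with Calpha")
    fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    return Structure(os.path.basename(path).rsplit(".", 1)[0], chain, residues, fmt)


def write_pdb(structure: Structure, path: str | os.PathLike,
              bfactors: Optional[dict] = None) -> None:
    """Write a minimal PDB file.

    ``bfactors`` maps residue ordinal to a scalar placed in the B-factor
    column of every atom of that residue (occupancy / conservation /
    enrichment annotation); unlisted residues get 0.00.
    """
    bfactors = bfactors or {}
    lines = []
    serial = 0
    for r in structure.residues:
        b = float(bfactors.get(r.ordinal, 0.0))
        aa3 = AA1_TO_3.get(r.aa1, "UNK")
        for name, xyz in r.heavy_atoms:
            serial += 1
            nm = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {nm:<4s} {aa3:>3s} {structure.chain:1s}"
                f"{r.author_number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {name[0]:>2s}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_stride(structure: Structure, sse: SSEAssignment,
                 path: str | os.PathLike) -> None:
    """Write an SSE assignment as STRIDE-style ASG records.

    Lets generated fixtures stand in for real STRIDE output, so the same
    ``--sse`` path works for synthetic and experimental structures.
    """
    names = {"H": "AlphaHelix", "E": "Strand", "C": "Coil"}
    with open(path, "w") as fh:
        fh.write("REM  |---Residue---|    |--Structure--|\n")
        for r in structure.residues:
            code = sse[r.ordinal]
            fh.write(
                f"ASG  {AA1_TO_3.get(r.aa1, 'UNK')} {structure.chain} "
                f"{r.author_number:4d} {r.ordinal:4d}    {code}"
                f"    {names[code]:<11s}   360.00    360.00       0.0\n"
            )


# ---------------------------------------------------------------------------
# STRIDE / DSSP parsing


def _parse_stride(lines, chain):
    out = {}
    for ln in lines:
        if not ln.startswith("ASG"):
            continue
        parts = ln.split()
        # ASG  resname chain author_num ordinal code ...
        if len(parts) < 6:
            continue
        ch = parts[2]
        if chain is not None and ch != chain and ch != "-":
            continue
        try:
            num = int(parts[3])
        except ValueError:
            continue
        out[num] = parts[5]
    return out


def _parse_dssp(lines, chain):
    out = {}
    in_table = False
    for ln in lines:
        if ln.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(ln) < 17:
            continue
        ch = ln[11].strip()
        if chain is not None and ch and ch != chain:
            continue
        numfield = ln[5:10].strip()
        if not numfield:  # chain break line
            continue
        try:
            num = int(numfield)
        except ValueError:
            continue
        code = ln[16].strip() or "C"
        out[num] = code
    return out


def read_sse_file(path: str | os.PathLike, structure: Structure) -> SSEAssignment:
    """Parse a STRIDE (detailed) or DSSP (classic) output file.

    Codes are collapsed to 3 classes (G/H/I -> H, E/B -> E, rest -> C);
    residues of the structure absent from the file default to C. Residues
    are matched by author number on the structure's chain.
    """
    with open(path) as fh:
        lines = fh.readlines()
    is_stride = any(ln.startswith(("ASG", "REM  |---Residue---|")) for ln in lines)
    if is_stride:
        codes = _parse_stride(lines, structure.chain)
        source = "stride-file"
    else:
        codes = _parse_dssp(lines, structure.chain)
        source = "dssp-file"
    present = [r.author_number for r in structure.residues if r.author_number in codes]
    if not present:
        raise ValueError(f"{path}: no residues overlap structure {structure.id}")
    classes = "".join(
        SSE_COLLAPSE.get(codes.get(r.author_number, "C"), "C")
        for r in structure.residues
    )
    return SSEAssignment(classes, source)


# ---------------------------------------------------------------------------
# Builtin dihedral-window assigner

# Ramachandran basins (degrees). Standard windows; helical covers alpha
# (and, loosely, 3_10); strand covers the extended beta region including
# the psi wrap-around near 180.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-170.0, -70.0)
STRAND_PSI_HI = (80.0, 180.0)
STRAND_PSI_LO = (-180.0, -170.0)

_WINDOW = 4  # consecutive in-basin residues required to call a segment class


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(structure: Structure):
    """Per-residue (phi, psi) in degrees; None where undefined/missing atoms."""
    n = len(structure)
    phi = [None] * n
    psi = [None] * n
    bb = []
    for r in structure.residues:
        bb.append((r.atom("N"), r.atom("CA"), r.atom("C")))
    for i in range(n):
        Ni, CAi, Ci = bb[i]
        if i > 0:
            Cp = bb[i - 1][2]
            if all(a is not None for a in (Cp, Ni, CAi, Ci)):
                phi[i] = dihedral(Cp, Ni, CAi, Ci)
        if i < n - 1:
            Nn = bb[i + 1][0]
            if all(a is not None for a in (Ni, CAi, Ci, Nn)):
                psi[i] = dihedral(Ni, CAi, Ci, Nn)
    return phi, psi


def _in_helix_basin(phi, psi):
    return (phi is not None and psi is not None
            and HELIX_PHI[0] <= phi <= HELIX_PHI[1]
            and HELIX_PSI[0] <= psi <= HELIX_PSI[1])


def _in_strand_basin(phi, psi):
    return (phi is not None and psi is not None
            and STRAND_PHI[0] <= phi <= STRAND_PHI[1]
            and (STRAND_PSI_HI[0] <= psi <= STRAND_PSI_HI[1]
                 or STRAND_PSI_LO[0] <= psi <= STRAND_PSI_LO[1]))


def assign_sse_builtin(structure: Structure) -> SSEAssignment:
    """Fallback 3-class assigner from backbone dihedrals.

    A residue is classified H (or E) when it lies inside a run of at least
    4 consecutive residues whose phi/psi fall in the helical (or strand)
    Ramachandran basin; everything else is C. Raises when more than 20% of
    residues lack the backbone atoms needed for any dihedral.
    """
    n = len(structure)
    if n < 5:
        raise ValueError("need at least 5 residues")
    phi, psi = backbone_dihedrals(structure)
    defined = sum(1 for i in range(1, n - 1) if phi[i] is not None and psi[i] is not None)
    if n > 2 and defined < 0.8 * (n - 2):
        raise ValueError("too many residues missing backbone atoms (>20%)")
    raw = []
    for i in range(n):
        if _in_helix_basin(phi[i], psi[i]):
            raw.append("H")
        elif _in_strand_basin(phi[i], psi[i]):
            raw.append("E")
        else:
            raw.append("C")
    out = ["C"] * n
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        if raw[i] in "HE" and j - i >= _WINDOW:
            out[i:j] = raw[i] * (j - i)
        i = j
    return SSEAssignment("".join(out), "builtin")
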