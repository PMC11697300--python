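"""GRN-indexed consensus contacts.

Per-structure heavy-atom residue contacts (closest heavy-atom pair under
a 4 A cutoff, sequence separation >= s_min) are aggregated over GRN
labels into a consensus matrix of contact frequencies, and optionally
coarse-grained to the segment level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from gaingrn.grnindex import GRNMap, parse_label
from gaingrn.structio import Structure

DEFAULT_CUTOFF = 4.0   # Angstrom, heavy-atom distance
DEFAULT_S_MIN = 4      # minimum sequence separation |i - j|


@dataclass
class ContactSet:
    structure_id: str
    pairs: set            # {(i, j) ordinals, i < j}
    cutoff: float
    s_min: int


@dataclass
class ConsensusContactMatrix:
    frequencies: dict     # (label1, label2) str pair, sorted -> frequency
    n_domains: int
    dropped_unlabeled: int = 0

    def to_long(self) -> pd.DataFrame:
        rows = [{"label1": a, "label2": b, "frequency": f}
                for (a, b), f in sorted(self.frequencies.items())]
        return pd.DataFrame(rows, columns=["label1", "label2", "frequency"])

    def to_square(self) -> pd.DataFrame:
        labels = sorted({l for pair in self.frequencies for l in pair},
                        key=lambda s: parse_label(s).sort_key())
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for (a, b), f in self.frequencies.items():
            m.loc[a, b] = f
            m.loc[b, a] = f
        return m


@dataclass
class SegmentContactMatrix:
    weights: dict         # (seg1, seg2), seg1 <= seg2 -> summed frequency
    within: dict = field(default_factory=dict)  # seg -> within-segment weight


def residue_contacts(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                     s_min: int = DEFAULT_S_MIN) -> ContactSet:
    """Residue pairs whose closest heavy atoms are under ``cutoff``.

    Pairs closer than ``s_min`` in sequence are excluded (they are in
    contact trivially and would dominate the consensus).
    """
    coords = []
    owner = []
    for r in structure.residues:
        for _, xyz in r.heavy_atoms:
            coords.append(xyz)
            owner.append(r.ordinal)
    if not coords:
        raise ValueError(f"{structure.id}: no heavy atoms")
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    tree = cKDTree(coords)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        i, j = int(owner[a]), int(owner[b])
        if i == j:
            continue
        i, j = (i, j) if i < j else (j, i)
        if j - i >= s_min:
            pairs.add((i, j))
    return ContactSet(structure.id, pairs, cutoff, s_min)


def consensus_contacts(contactsets: Sequence[ContactSet],
                       grnmaps: Sequence[GRNMap]) -> ConsensusContactMatrix:
    """Aggregate per-structure contacts over GRN labels.

    frequency(L1, L2) = number of domains in which residues labeled L1
    and L2 touch, divided by the total domain count. Contacts involving
    an unlabeled residue are dropped and tallied.
    """
    if len(contactsets) != len(grnmaps):
        raise ValueError("one GRN map per contact set required")
    counts: dict = {}
    dropped = 0
    for cs, gm in zip(contactsets, grnmaps):
        if cs.structure_id != gm.structure_id:
            raise ValueError(f"id mismatch: {cs.structure_id} vs {gm.structure_id}")
        seen = set()
        for i, j in cs.pairs:
            li, lj = gm.label_of(i), gm.label_of(j)
            if li is None or lj is None:
                dropped += 1
                continue
            key = tuple(sorted((str(li), str(lj)),
                               key=lambda s: parse_label(s).sort_key()))
            seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = len(contactsets)
    freqs = {k: c / n for k, c in counts.items()}
    return ConsensusContactMatrix(freqs, n, dropped)


def coarse_grain(matrix: ConsensusContactMatrix) -> SegmentContactMatrix:
    """Sum consensus frequencies per segment pair.

    Within-segment weight goes to a separate diagonal table; the sum (not
    the mean) is used so a segment pair with many conserved contacts
    outweighs one with a single contact.
    """
    weights: dict = {}
    within: dict = {}
    for (a, b), f in matrix.frequencies.items():
        sa, sb = parse_label(a).segment, parse_label(b).segment
        if sa == sb:
            within[sa] = within.get(sa, 0.0) + f
            continue
        key = tuple(sorted((sa, sb)))
        weights[key] = weights.get(key, 0.0) + f
    return SegmentContactMatrix(weights, within)
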