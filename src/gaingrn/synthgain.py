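"""Synthetic GAIN-like structures with planted ground truth.

Builds single-chain backbones (N, CA, C, O) by internal-coordinate chain
extension with ideal bond geometry and per-residue phi/psi dihedrals:
alpha-helical segments (phi -57, psi -47), extended strands (phi -120,
psi 130) and irregular coil linkers. Each built domain carries its planted
secondary structure, GRN truth labels, segment spans and anchors, so the
detector, aligner, template builder and indexer can all be tested against
known answers without any external data. No physical realism is claimed
beyond what those tests need; in particular sheet packing is not modeled
— inter-residue contacts needed by tests are planted explicitly as
pseudo side-chain atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from gaingrn.structio import Residue, SSEAssignment, Structure
from gaingrn.grnindex import (GPS_INDICES, GRNLabel, GRNMap, HELIX_SEGMENTS,
                              STRAND_SEGMENTS, canonical_loop_id)

# ideal backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)

# residues drawn for unconstrained positions; excludes G/P (segment
# breakers used by the split rules) and H/L/S/T (so the planted GPS triad
# is the only H-L-[T/S] motif in the chain)
BACKGROUND_ALPHABET = "ACDEFIKMNQRVWY"

# planted conserved anchor residue per segment
DEFAULT_ANCHOR_AA = {
    "H1": "F", "H2": "Y", "H3": "Q", "H4": "N", "H5": "K", "H6": "E",
    "S1": "V", "S2": "I", "S3": "F", "S4": "Y", "S5": "W", "S6": "V",
    "S7": "I", "S8": "F", "S9": "Y", "S10": "W", "S11": "V", "S12": "I",
    "S13": "F", "S14": "W",
}


@dataclass(frozen=True)
class SegmentPlan:
    kind: str        # helix | strand | gps
    seg_id: str      # H1..H6 / S1..S14 / GPS
    length: int
    anchor_offset: Optional[int] = None  # 0-based within segment; default middle


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint of a synthetic GAIN-like chain.

    Valid-GAIN presets keep 2-6 helices and 12-14 strands plus the GPS
    triad inserted between S13 and S14.
    """

    name: str
    segments: tuple  # of SegmentPlan, in chain order
    loop_len: int = 10
    nterm_tail: int = 6
    cterm_tail: int = 8
    anchor_aa: dict = field(default_factory=lambda: dict(DEFAULT_ANCHOR_AA))

    @property
    def helix_count(self) -> int:
        return sum(1 for s in self.segments if s.kind == "helix")

    @property
    def strand_count(self) -> int:
        return sum(1 for s in self.segments if s.kind == "strand")


@dataclass
class SyntheticDomain:
    structure: Structure
    sse_truth: SSEAssignment
    grn_truth: GRNMap
    spec: ArchitectureSpec
    segment_spans: dict = field(default_factory=dict)   # seg_id -> (start, end)
    anchors: dict = field(default_factory=dict)         # seg_id -> ordinal
    gps: Optional[tuple] = None
    subdomainA_span: Optional[tuple] = None
    subdomainB_span: Optional[tuple] = None


# ---------------------------------------------------------------------------
# internal-coordinate backbone building


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d from a-b-c with given internal coordinates."""
    angle = math.radians(angle_deg)
    tors = -math.radians(torsion_deg)  # frame below is left-handed w.r.t. the
    # conventional torsion sign, so negate to get IUPAC-signed dihedrals
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-math.cos(angle),
                          math.sin(angle) * math.cos(tors),
                          math.sin(angle) * math.sin(tors)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phis: Sequence[float], psis: Sequence[float]) -> list:
    """Backbone atoms for n residues from per-residue (phi, psi).

    phi of the first residue and psi of the last are unused (undefined).
    Returns a list of dicts with keys N, CA, C, O.
    """
    n = len(phis)
    if n < 3:
        raise ValueError("need at least 3 residues")
    atoms = []
    N0 = np.zeros(3)
    CA0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    C0 = CA0 + B_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    atoms.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = atoms[-1]
        Ni = _place(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psis[i - 1])
        CAi = _place(prev["CA"], prev["C"], Ni, B_N_CA, A_C_N_CA, OMEGA)
        Ci = _place(prev["C"], Ni, CAi, B_CA_C, A_N_CA_C, phis[i])
        atoms.append({"N": Ni, "CA": CAi, "C": Ci})
    for i in range(n):
        if i < n - 1:
            psi = psis[i]
        else:
            psi = psis[i] if psis[i] is not None else -40.0
        a = atoms[i]
        a["O"] = _place(a["N"], a["CA"], a["C"], B_C_O, A_CA_C_O, psi + 180.0)
    return atoms


def build_segment(kind: str, n: int) -> np.ndarray:
    """Ideal-geometry segment backbone; returns Calpha coordinates (n, 3).

    Helices rise ~1.5 A per residue about their axis with ~100 deg twist;
    strands extend ~3.3 A per residue.
    """
    if n < 3:
        raise ValueError("segment needs at least 3 residues")
    phi, psi = HELIX_PHI_PSI if kind == "helix" else STRAND_PHI_PSI
    atoms = build_backbone([phi] * n, [psi] * n)
    return np.vstack([a["CA"] for a in atoms])


# ---------------------------------------------------------------------------
# canonical spatial layout
#
# Each segment id always occupies the same place in space, whatever the
# architecture: subdomain A helices sit on a 2x3 bundle grid, subdomain B
# strands form two stacked sheets (~4.8 A strand spacing, ~10 A sheet
# separation) with consecutive strands on alternating sheets, and the GPS
# triad sits in the crossover before S14. Segment deletion therefore leaves
# every other segment where it was — the property the spatial indexing
# scheme relies on.

HELIX_GRID = {"H1": (-46.0, 0.0), "H2": (-46.0, 11.0), "H3": (-36.0, 0.0),
              "H4": (-36.0, 11.0), "H5": (-26.0, 0.0), "H6": (-26.0, 11.0)}
HELIX_DIR = {"H1": 1.0, "H2": -1.0, "H3": 1.0, "H4": -1.0, "H5": 1.0, "H6": -1.0}
SHEET_SPACING = 4.8
SHEET_SEP = 10.0
GPS_CENTER = (28.8, 16.0, 10.0)


def _unit(v):
    return v / np.linalg.norm(v)


def _min_rotation(a, b):
    """Smallest rotation taking unit vector a to unit vector b (Rodrigues)."""
    a, b = _unit(np.asarray(a, float)), _unit(np.asarray(b, float))
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    s = np.linalg.norm(c)
    if s < 1e-12:
        if d > 0:
            return np.eye(3)
        p = _unit(np.cross(a, [1.0, 0.0, 0.0]) if abs(a[0]) < 0.9
                  else np.cross(a, [0.0, 1.0, 0.0]))
        K = np.array([[0, -p[2], p[1]], [p[2], 0, -p[0]], [-p[1], p[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    axis = c / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    theta = math.atan2(s, d)
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * K @ K


def _segment_placement(seg: SegmentPlan):
    z = np.array([0.0, 0.0, 1.0])
    if seg.kind == "helix":
        x, y = HELIX_GRID[seg.seg_id]
        return np.array([x, y, 0.0]), z * HELIX_DIR[seg.seg_id]
    if seg.kind == "strand":
        k = int(seg.seg_id[1:])
        col, sheet = (k - 1) // 2, (k - 1) % 2
        d = 1.0 if sheet == 0 else -1.0
        return np.array([col * SHEET_SPACING, sheet * SHEET_SEP, 0.0]), z * d
    return np.array(GPS_CENTER), z


def _place_piece(kind: str, n: int, center, direction):
    """Ideal segment backbone oriented along ``direction`` at ``center``."""
    phi, psi = HELIX_PHI_PSI if kind == "helix" else STRAND_PHI_PSI
    atoms = build_backbone([phi] * n, [psi] * n)
    ca = np.vstack([a["CA"] for a in atoms])
    R = _min_rotation(ca[-1] - ca[0], direction)
    cen = ca.mean(axis=0)
    return [{k: R @ (v - cen) + np.asarray(center, float) for k, v in a.items()}
            for a in atoms]


def _route_loop(p0, p1, n: int):
    """n pseudo-backbone residues on a bulged path strictly between p0, p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length = np.linalg.norm(d)
    dhat = _unit(d) if length > 1e-9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(dhat, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 0.1:
        perp = np.cross(dhat, [1.0, 0.0, 0.0])
    perp = _unit(perp)
    perp2 = _unit(np.cross(dhat, perp))
    bulge = max(2.0, 0.35 * n)

    def path(t):
        return p0 + t * d + bulge * math.sin(math.pi * t) * perp

    out = []
    dt = 1.0 / (n + 1)
    for i in range(1, n + 1):
        t = i * dt
        ca = path(t)
        tang = _unit(path(min(t + 0.5 * dt, 1.0)) - path(max(t - 0.5 * dt, 0.0)))
        jit = perp2 * (0.35 if i % 2 else -0.35)
        out.append({
            "N": ca - 0.6 * tang + jit,
            "CA": ca,
            "C": ca + 0.6 * tang + jit,
            "O": ca + 0.6 * tang + jit + 1.2 * perp2,
        })
    return out


# ---------------------------------------------------------------------------
# domain assembly


def _segment_order(spec: ArchitectureSpec):
    """(tag, length, seg_id) items in chain order, including linkers."""
    items = [("tail", spec.nterm_tail, None)]
    prev_id = None
    for seg in spec.segments:
        if prev_id is not None:
            items.append(("loop", spec.loop_len, canonical_loop_id(prev_id, seg.seg_id)))
        items.append((seg.kind, seg.length, seg.seg_id))
        prev_id = seg.seg_id
    items.append(("tail", spec.cterm_tail, "s14tm1" if prev_id == "S14" else None))
    return items


def build_domain(spec: ArchitectureSpec, seed: int = 0) -> SyntheticDomain:
    """Assemble the full chain and its planted ground truth.

    Coordinates are a deterministic function of the plan; the sequence is
    drawn from the background alphabet under ``seed`` except at planted
    positions (segment anchors, GPS triad H-L-T).
    """
    rng = np.random.default_rng(seed)
    items = _segment_order(spec)

    # place every structured segment at its canonical spatial position
    placed = {}
    for seg in spec.segments:
        center, direction = _segment_placement(seg)
        kind = "helix" if seg.kind == "helix" else "strand"
        placed[seg.seg_id] = _place_piece(kind, seg.length, center, direction)

    seg_ids = [s.seg_id for s in spec.segments]
    first_ca = {sid: placed[sid][0]["CA"] for sid in seg_ids}
    last_ca = {sid: placed[sid][-1]["CA"] for sid in seg_ids}

    atoms = []
    classes = []
    spans = {}
    loop_membership = {}
    pos = 0
    prev_sid = None
    for idx, (tag, length, name) in enumerate(items):
        if length == 0:
            continue
        start = pos + 1
        if tag in ("helix", "strand", "gps"):
            cls = {"helix": "H", "strand": "E", "gps": "C"}[tag]
            atoms.extend(placed[name])
            classes.extend(cls * length)
            spans[name] = (start, start + length - 1)
            prev_sid = name
        else:
            # linker: tail or inter-segment loop
            following = next((it[2] for it in items[idx + 1:]
                              if it[0] in ("helix", "strand", "gps")), None)
            if prev_sid is None:       # N-terminal tail
                p1 = first_ca[following]
                p0 = p1 + np.array([-1.0, -1.0, 0.0]) * 2.2 * (length + 1)
            elif following is None:    # C-terminal tail
                p0 = last_ca[prev_sid]
                p1 = p0 + np.array([1.0, 1.0, 0.0]) * 2.2 * (length + 1)
            else:
                p0 = last_ca[prev_sid]
                p1 = first_ca[following]
            atoms.extend(_route_loop(p0, p1, length))
            classes.extend("C" * length)
            if name is not None:
                for o in range(start, start + length):
                    loop_membership[o] = name
        pos += length

    n = pos

    # sequence
    seq = list(rng.choice(list(BACKGROUND_ALPHABET), size=n))
    anchors = {}
    for seg in spec.segments:
        s, e = spans[seg.seg_id]
        if seg.kind == "gps":
            seq[s - 1], seq[s], seq[s + 1] = "H", "L", "T"
            continue
        off = seg.anchor_offset if seg.anchor_offset is not None else seg.length // 2
        anchor = s + off
        anchors[seg.seg_id] = anchor
        aa = spec.anchor_aa.get(seg.seg_id)
        if aa:
            seq[anchor - 1] = aa

    residues = []
    for i in range(n):
        a = atoms[i]
        heavy = [("N", a["N"]), ("CA", a["CA"]), ("C", a["C"]), ("O", a["O"])]
        residues.append(Residue(i + 1, i + 1, seq[i], heavy, a["CA"]))
    structure = Structure(f"{spec.name}-{seed}", "A", residues, "synthetic")
    sse = SSEAssignment("".join(classes), "truth")

    # truth GRN map
    labels = {}
    for seg_id, anchor in anchors.items():
        s, e = spans[seg_id]
        for o in range(s, e + 1):
            labels[o] = GRNLabel(seg_id, 50 + (o - anchor))
    gps = None
    if "GPS" in spans:
        g = spans["GPS"][0]
        gps = (g, g + 1, g + 2)
        for o, idx in zip(gps, GPS_INDICES):
            labels[o] = GRNLabel("GPS", idx)
    truth = GRNMap(structure_id=structure.id, labels=labels,
                   loops=dict(loop_membership), templates=("truth", "truth"))

    helix_spans = [spans[s.seg_id] for s in spec.segments if s.kind == "helix"]
    strand_spans = [spans[s.seg_id] for s in spec.segments if s.kind == "strand"]
    dom = SyntheticDomain(
        structure=structure, sse_truth=sse, grn_truth=truth, spec=spec,
        segment_spans=spans, anchors=anchors, gps=gps,
        subdomainA_span=(helix_spans[0][0], helix_spans[-1][1]) if helix_spans else None,
        subdomainB_span=(strand_spans[0][0], strand_spans[-1][1]) if strand_spans else None,
    )
    return dom


def perturb(domain: SyntheticDomain, sigma: float, seed: int = 0) -> SyntheticDomain:
    """Isotropic Gaussian displacement of every atom; truth is unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    st = domain.structure
    residues = []
    for r in st.residues:
        heavy = []
        ca = None
        for name, xyz in r.heavy_atoms:
            moved = xyz + rng.normal(0.0, sigma, size=3)
            heavy.append((name, moved))
            if name == "CA":
                ca = moved
        residues.append(Residue(r.ordinal, r.author_number, r.aa1, heavy, ca))
    structure = Structure(st.id, st.chain, residues, "synthetic")
    out = replace(domain, structure=structure)
    out.grn_truth = replace(domain.grn_truth, structure_id=structure.id)
    return out


def ablate_gps(domain: SyntheticDomain) -> SyntheticDomain:
    """Mutate the planted H-L-T triad to A-A-A (breaks GPS criterion)."""
    if domain.gps is None:
        return domain
    st = domain.structure
    residues = [Residue(r.ordinal, r.author_number,
                        "A" if r.ordinal in domain.gps else r.aa1,
                        r.heavy_atoms, r.ca)
                for r in st.residues]
    structure = Structure(st.id + "-nogps", st.chain, residues, "synthetic")
    return replace(domain, structure=structure, gps=None)


def plant_contact(domain: SyntheticDomain, ordinal_a: int, ordinal_b: int,
                  distance: float = 3.5) -> SyntheticDomain:
    """Add CB pseudo-atoms so the two residues' closest heavy atoms sit at
    ``distance`` Angstrom, planting a residue-residue contact."""
    st = domain.structure
    ca_a = st[ordinal_a].ca
    ca_b = st[ordinal_b].ca
    v = ca_b - ca_a
    d = np.linalg.norm(v)
    u = v / d
    mid = (ca_a + ca_b) / 2.0
    pa = mid - u * (distance / 2.0)
    pb = mid + u * (distance / 2.0)
    residues = []
    for r in st.residues:
        heavy = list(r.heavy_atoms)
        if r.ordinal == ordinal_a:
            heavy.append(("CB", pa))
        elif r.ordinal == ordinal_b:
            heavy.append(("CB", pb))
        residues.append(Residue(r.ordinal, r.author_number, r.aa1, heavy, r.ca))
    return replace(domain, structure=Structure(st.id, st.chain, residues, "synthetic"))


# ---------------------------------------------------------------------------
# presets (architectures mirror the observed archetypes: full six-helix
# bundles, minimal two-helix subdomain A, and a PKD-like reduced form)


def _helices(ids_lengths):
    return [SegmentPlan("helix", i, l) for i, l in ids_lengths]


def _strands(ids_lengths):
    return [SegmentPlan("strand", i, l) for i, l in ids_lengths]


def preset_canonical(loop_len: int = 10) -> ArchitectureSpec:
    """Six helices, 14 strands, GPS between S13 and S14."""
    segs = (
        _helices([("H1", 10), ("H2", 10), ("H3", 12), ("H4", 14), ("H5", 10), ("H6", 16)])
        + _strands([(f"S{k}", 7 if k % 2 else 8) for k in range(1, 14)])
        + [SegmentPlan("gps", "GPS", 3)]
        + _strands([("S14", 9)])
    )
    return ArchitectureSpec("canonical", tuple(segs), loop_len=loop_len)


def preset_minimal_a(loop_len: int = 10) -> ArchitectureSpec:
    """Two-helix subdomain A (H4 and H6 only), 13 strands."""
    segs = (
        _helices([("H4", 14), ("H6", 16)])
        + _strands([(f"S{k}", 7 if k % 2 else 8) for k in range(1, 13) if k != 4])
        + _strands([("S13", 7)])
        + [SegmentPlan("gps", "GPS", 3)]
        + _strands([("S14", 9)])
    )
    return ArchitectureSpec("minimal-a", tuple(segs), loop_len=loop_len)


def preset_pkd_like(loop_len: int = 10) -> ArchitectureSpec:
    """Four helices, 12 strands, extended S10/S14."""
    segs = (
        _helices([("H3", 12), ("H4", 14), ("H5", 10), ("H6", 16)])
        + _strands([(f"S{k}", 7 if k % 2 else 8) for k in (1, 2, 3, 5, 6, 8, 9)])
        + _strands([("S10", 12), ("S11", 7), ("S12", 8), ("S13", 7)])
        + [SegmentPlan("gps", "GPS", 3)]
        + _strands([("S14", 12)])
    )
    return ArchitectureSpec("pkd-like", tuple(segs), loop_len=loop_len)


PRESETS = {
    "canonical": preset_canonical,
    "minimal-a": preset_minimal_a,
    "pkd-like": preset_pkd_like,
}


def make_registry_for_spec(spec: ArchitectureSpec, group: Optional[str] = None,
                           seed: int = 0):
    """Template registry (one A and one B template) from a noise-free
    domain built from ``spec``, with the planted anchors."""
    from gaingrn.templatebuild import TemplateEntry, TemplateRegistry

    dom = build_domain(spec, seed=seed)
    group = group or spec.name
    registry = TemplateRegistry()
    for sub, span in (("A", dom.subdomainA_span), ("B", dom.subdomainB_span)):
        if span is None:
            continue
        want = HELIX_SEGMENTS if sub == "A" else STRAND_SEGMENTS + ("GPS",)
        segments = {sid: sp for sid, sp in dom.segment_spans.items() if sid in want}
        anchors = {sid: a for sid, a in dom.anchors.items() if sid in segments}
        entry = TemplateEntry(
            id=f"{group}-{sub}", subdomain=sub, structure=dom.structure,
            sse=dom.sse_truth, span=span, segments=segments,
            anchors=anchors, group=group,
        )
        registry.add(entry, default_for=group)
    return registry
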