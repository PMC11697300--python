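"""Generic residue number (GRN) grammar and assignment.

A GRN is a segment identifier plus a numeric index separated by a dot,
e.g. ``H6.50``: the ``.50`` position is the segment anchor (its most
conserved residue across the ensemble) and all other residues are indexed
relative to it, decreasing N-terminally and increasing C-terminally. The
GPS triad uses the ``GPS.-2 / GPS.-1 / GPS.+1`` notation around the
cleavage site. Loop residues are not individually indexed; they carry the
membership of one of the 21 inter-segment loop regions (``h1h2`` ...
``s14tm1``).

Assignment matches a detected GAIN domain onto its subdomain templates by
pairwise structural alignment: the residue matching each template anchor
becomes ``.50`` (or an offset-anchored index when the anchor column
itself is unmatched), and the rest of the query's secondary-structure
block is enumerated from there. When one query block absorbs two template
segments, a hierarchical splitting rule decides the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from gaingrn.align3d import align_pair
from gaingrn.structio import SSEAssignment, Structure, backbone_dihedrals

HELIX_SEGMENTS = tuple(f"H{i}" for i in range(1, 7))
STRAND_SEGMENTS = tuple(f"S{i}" for i in range(1, 15))
STRUCTURED_SEGMENTS = HELIX_SEGMENTS + STRAND_SEGMENTS
GPS_INDICES = (-2, -1, 1)

#: the 21 loop regions connecting structured segments
LOOP_IDS = (
    "h1h2", "h2h3", "h3h4", "h4h5", "h5h6", "h6s1",
    "s1s2", "s2s3", "s3s4", "s4s5", "s5s6", "s6s7", "s7s8", "s8s9",
    "s9s10", "s10s11", "s11s12", "s12s13", "s13gps", "gpss14", "s14tm1",
)

MIN_INDEX, MAX_INDEX = 1, 99

# canonical dihedral distributions (mean, sd in degrees) used by the
# merged-segment outlier rule when no ensemble estimate is available
CANONICAL_DIHEDRAL_STATS = {
    "H": {"phi": (-63.0, 10.0), "psi": (-42.0, 10.0)},
    "E": {"phi": (-120.0, 25.0), "psi": (130.0, 25.0)},
}
OUTLIER_SD = 5.0

_LABEL_RE = re.compile(r"^(H[1-6]|S([1-9]|1[0-4]))\.([1-9][0-9]?)$")
_GPS_RE = re.compile(r"^GPS\.(-2|-1|\+1)$")


@dataclass(frozen=True)
class GRNLabel:
    """A structured-segment or GPS generic residue number."""

    segment: str
    index: int

    def __str__(self) -> str:
        if self.segment == "GPS":
            return f"GPS.{self.index:+d}"
        return f"{self.segment}.{self.index}"

    def sort_key(self):
        order = {s: i for i, s in enumerate(STRUCTURED_SEGMENTS + ("GPS",))}
        return (order[self.segment], self.index)


def format_label(label: GRNLabel) -> str:
    return str(label)


def parse_label(text: str) -> GRNLabel:
    """Parse the canonical string form; raises ValueError on anything else."""
    m = _GPS_RE.match(text)
    if m:
        return GRNLabel("GPS", int(m.group(1)))
    m = _LABEL_RE.match(text)
    if m:
        return GRNLabel(m.group(1), int(m.group(3)))
    raise ValueError(f"not a valid GRN label: {text!r}")


def all_labels():
    """Every admissible structured/GPS label (for grammar checks)."""
    out = [GRNLabel(s, i) for s in STRUCTURED_SEGMENTS
           for i in range(MIN_INDEX, MAX_INDEX + 1)]
    out.extend(GRNLabel("GPS", i) for i in GPS_INDICES)
    return out


def canonical_loop_id(prev_seg: str, next_seg: str) -> str:
    """Loop region id between two flanking segments (``h1h2`` style)."""
    return f"{prev_seg.lower()}{next_seg.lower()}"


@dataclass
class SplitDecision:
    span: tuple            # merged block span (start, end)
    split_residue: Optional[int]
    rule: str              # coil | dihedral-outlier | pro-gly | manual | unsplit


@dataclass
class GRNMap:
    """Residue-to-GRN assignment for one domain."""

    structure_id: str
    labels: dict = field(default_factory=dict)  # ordinal -> GRNLabel
    loops: dict = field(default_factory=dict)   # ordinal -> loop region id
    templates: tuple = (None, None)             # (A template id, B template id)
    offsets: list = field(default_factory=list)
    splits: list = field(default_factory=list)

    def label_of(self, ordinal: int) -> Optional[GRNLabel]:
        return self.labels.get(ordinal)

    def ordinal_of(self, label: GRNLabel) -> Optional[int]:
        for o, l in self.labels.items():
            if l == label:
                return o
        return None

    def segments_present(self):
        return sorted({l.segment for l in self.labels.values()},
                      key=lambda s: (STRUCTURED_SEGMENTS + ("GPS",)).index(s))

    def validate(self) -> None:
        """Structured-label injectivity and within-segment contiguity."""
        seen = {}
        for o, l in self.labels.items():
            if l in seen:
                raise ValueError(f"label {l} assigned to ordinals {seen[l]} and {o}")
            seen[l] = o
        by_seg = {}
        for o, l in self.labels.items():
            if l.segment != "GPS":
                by_seg.setdefault(l.segment, []).append((o, l.index))
        for seg, pairs in by_seg.items():
            pairs.sort()
            ords = [p[0] for p in pairs]
            idxs = [p[1] for p in pairs]
            for k in range(1, len(pairs)):
                if ords[k] - ords[k - 1] != idxs[k] - idxs[k - 1]:
                    raise ValueError(f"non-contiguous indices in {seg}")

    def to_records(self, structure: Optional[Structure] = None):
        """Sorted (ordinal, author_number, aa1, label, segment) rows."""
        rows = []
        ords = sorted(set(self.labels) | set(self.loops))
        for o in ords:
            lab = self.labels.get(o)
            rows.append({
                "ordinal": o,
                "author_number": structure[o].author_number if structure else o,
                "aa1": structure[o].aa1 if structure else "X",
                "grn_label": str(lab) if lab else "",
                "segment": lab.segment if lab else self.loops.get(o, ""),
            })
        return rows


# ---------------------------------------------------------------------------
# anchor resolution and segment splitting


def resolve_offset(segment_matches: dict, anchor: int):
    """Anchor a segment whose template anchor column is unmatched.

    ``segment_matches`` maps template ordinal -> query ordinal for one
    segment. The match nearest the anchor (tie -> the N-terminal side) is
    taken as reference and indexed ``50 + (matched - anchor)``, e.g. three
    residues N-terminal of the anchor gives ``.47``. Returns
    ``(query_ordinal, start_index, offset)``.
    """
    if not segment_matches:
        raise ValueError("segment has no matches")
    best = min(segment_matches, key=lambda t: (abs(t - anchor), t))
    offset = best - anchor
    return segment_matches[best], 50 + offset, offset


def _circ_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def split_merged(span: tuple, anchor_q1: int, anchor_q2: int,
                 sse: SSEAssignment, phi: Sequence, psi: Sequence,
                 sequence: str, kind: str = "H",
                 stats: Optional[dict] = None,
                 manual_split: Optional[int] = None) -> SplitDecision:
    """Split one detected block that matched two template anchors.

    The region strictly between the anchors is scanned with rules in
    decreasing priority: (1) a coil residue, (2) backbone angles more
    than five standard deviations from the element's dihedral
    distribution, (3) a proline or glycine, (4) a manually defined
    truncation element. With no applicable rule the block stays unsplit
    and is flagged for curation.
    """
    if not (span[0] <= anchor_q1 < anchor_q2 <= span[1]):
        raise ValueError("anchors must lie inside the block, in order")
    stats = stats or CANONICAL_DIHEDRAL_STATS
    between = range(anchor_q1 + 1, anchor_q2)
    for o in between:
        if sse[o] == "C":
            return SplitDecision(span, o, "coil")
    mu_phi, sd_phi = stats[kind]["phi"]
    mu_psi, sd_psi = stats[kind]["psi"]
    for o in between:
        ph, ps = phi[o - 1], psi[o - 1]
        if ph is not None and _circ_diff(ph, mu_phi) > OUTLIER_SD * sd_phi:
            return SplitDecision(span, o, "dihedral-outlier")
        if ps is not None and _circ_diff(ps, mu_psi) > OUTLIER_SD * sd_psi:
            return SplitDecision(span, o, "dihedral-outlier")
    for o in between:
        if sequence[o - 1] in "PG":
            return SplitDecision(span, o, "pro-gly")
    if manual_split is not None and anchor_q1 < manual_split < anchor_q2:
        return SplitDecision(span, manual_split, "manual")
    return SplitDecision(span, None, "unsplit")


# ---------------------------------------------------------------------------
# assignment


def _query_block(sse: SSEAssignment, ordinal: int, kind: str, span: tuple):
    """Maximal run of ``kind`` containing ``ordinal`` within ``span``."""
    if sse[ordinal] != kind:
        return (ordinal, ordinal)
    lo = ordinal
    while lo - 1 >= span[0] and sse[lo - 1] == kind:
        lo -= 1
    hi = ordinal
    while hi + 1 <= span[1] and sse[hi + 1] == kind:
        hi += 1
    return (lo, hi)


def assign_grn(domain, registry, sse: SSEAssignment,
               d_match: float = 3.0) -> GRNMap:
    """Assign GRN labels to every ordered residue of a valid GAIN domain.

    The domain is pairwise-aligned to its subdomain A and B templates
    (resolved by group, or by lowest alignment RMSD when ungrouped); for
    each template segment the residue matching the template anchor is
    labeled .50 (offset-anchored when the anchor column is unmatched) and
    the query's secondary-structure block is enumerated from there.
    """
    if not getattr(domain, "valid", True):
        raise ValueError(f"invalid domain ({domain.failure_reason})")
    st = domain.structure
    tmpl_a, tmpl_b = registry.resolve(group=domain.group, structure=st, sse=sse)
    grn = GRNMap(structure_id=st.id,
                 templates=(tmpl_a.id if tmpl_a else None,
                            tmpl_b.id if tmpl_b else None))

    phi, psi = backbone_dihedrals(st)
    # anchored[(block)] -> list of (seg_id, q0, idx0, kind)
    anchored_by_block = {}
    seg_kind = {}
    for sub, tmpl, span in (("A", tmpl_a, domain.subdomainA_span),
                            ("B", tmpl_b, domain.subdomainB_span)):
        if tmpl is None or span is None:
            continue
        res = align_pair(st, tmpl.structure, sse_a=sse, sse_b=tmpl.sse,
                         span_a=span, span_b=tmpl.span, d_match=d_match)
        q_by_t = {t: q for q, t in res.matches}
        for seg_id, (ts, te) in sorted(tmpl.segments.items()):
            if seg_id == "GPS":
                continue
            anchor = tmpl.anchors.get(seg_id)
            if anchor is None:
                continue
            seg_matches = {t: q_by_t[t] for t in range(ts, te + 1) if t in q_by_t}
            if not seg_matches:
                continue  # segment absent from this domain
            if anchor in seg_matches:
                q0, idx0, off = seg_matches[anchor], 50, 0
            else:
                q0, idx0, off = resolve_offset(seg_matches, anchor)
                grn.offsets.append((seg_id, off))
            kind = "H" if seg_id.startswith("H") else "E"
            seg_kind[seg_id] = kind
            block = _query_block(sse, q0, kind, span)
            anchored_by_block.setdefault(block, []).append((seg_id, q0, idx0, kind))

    # resolve blocks that captured more than one template segment
    pieces = []  # (seg_id, block_span, q0, idx0)
    for block, entries in anchored_by_block.items():
        entries.sort(key=lambda e: e[1])
        if len(entries) == 1:
            seg_id, q0, idx0, _ = entries[0]
            pieces.append((seg_id, block, q0, idx0))
            continue
        bounds = [block[0]]
        for (s1, q1, i1, k1), (s2, q2, i2, k2) in zip(entries, entries[1:]):
            dec = split_merged(block, q1, q2, sse, phi, psi, st.sequence, kind=k1)
            grn.splits.append(dec)
            if dec.split_residue is None:
                split_at = (q1 + q2) // 2  # flagged unsplit: fall back to midpoint
                bounds.extend([split_at, split_at + 1])
            elif dec.rule == "coil":
                bounds.extend([dec.split_residue - 1, dec.split_residue + 1])
            else:
                bounds.extend([dec.split_residue - 1, dec.split_residue])
        bounds.append(block[1])
        for k, (seg_id, q0, idx0, _) in enumerate(entries):
            lo, hi = bounds[2 * k], bounds[2 * k + 1]
            pieces.append((seg_id, (lo, hi), q0, idx0))

    # enumerate labels over each piece
    for seg_id, (lo, hi), q0, idx0 in pieces:
        for o in range(lo, hi + 1):
            idx = idx0 + (o - q0)
            if MIN_INDEX <= idx <= MAX_INDEX:
                grn.labels[o] = GRNLabel(seg_id, idx)

    # GPS triad overrides whatever fell on those ordinals
    if getattr(domain, "gps", None):
        for o, idx in zip(domain.gps, GPS_INDICES):
            grn.labels[o] = GRNLabel("GPS", idx)

    _assign_loops(grn, domain)
    grn.validate()
    return grn


def _assign_loops(grn: GRNMap, domain) -> None:
    """Give unindexed residues their loop-region membership."""
    if not grn.labels:
        return
    st = domain.structure
    spans = {}
    for o, l in grn.labels.items():
        s, e = spans.get(l.segment, (o, o))
        spans[l.segment] = (min(s, o), max(e, o))
    ordered = sorted(spans.items(), key=lambda kv: kv[1][0])
    dom_start = domain.domain_span[0] if getattr(domain, "domain_span", None) else ordered[0][1][0]
    for (seg1, (_, e1)), (seg2, (s2, _)) in zip(ordered, ordered[1:]):
        lid = canonical_loop_id(seg1, seg2)
        for o in range(e1 + 1, s2):
            if o not in grn.labels:
                grn.loops[o] = lid
    last_seg, (_, last_end) = ordered[-1]
    if last_seg == "S14":
        for o in range(last_end + 1, len(st) + 1):
            grn.loops[o] = "s14tm1"


# ---------------------------------------------------------------------------
# ensemble tables


def conservation_table(maps: Sequence[GRNMap], sequences: dict):
    """Per-label residue frequencies and per-segment occupancy.

    ``sequences`` maps structure id -> one-letter sequence (ordinal k is
    position k of the string). Frequencies are counts divided by the total
    number of domains (an absent label counts as absent, not as a gap
    category). Returns ``(freq, occupancy)`` as DataFrame / Series.
    """
    import pandas as pd

    if not maps:
        raise ValueError("need at least one GRN map")
    n = len(maps)
    counts = {}
    seg_presence = {}
    for m in maps:
        seq = sequences[m.structure_id]
        for seg in m.segments_present():
            seg_presence[seg] = seg_presence.get(seg, 0) + 1
        for o, l in m.labels.items():
            aa = seq[o - 1]
            counts.setdefault(str(l), {}).setdefault(aa, 0)
            counts[str(l)][aa] += 1
    labels = sorted(counts, key=lambda s: parse_label(s).sort_key())
    aas = sorted({aa for d in counts.values() for aa in d})
    freq = pd.DataFrame(0.0, index=labels, columns=aas)
    for lab, d in counts.items():
        for aa, c in d.items():
            freq.loc[lab, aa] = c / n
    occupancy = pd.Series({s: seg_presence[s] / n for s in seg_presence},
                          name="occupancy").sort_index(
        key=lambda idx: [(STRUCTURED_SEGMENTS + ("GPS",)).index(s) for s in idx])
    return freq, occupancy
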