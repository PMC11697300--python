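"""Signal-based GAIN-domain detection.

The detector turns a 3-class secondary-structure string into a numeric
signal (+1 helix, -1 strand, 0 coil), smooths it by linear convolution
with a box kernel, and reads helix/strand segment blocks off the sign
structure of the smoothed signal. A GAIN domain is called when (i) a
helical subdomain A sits directly N-terminal of the most C-terminal
beta-strand run (subdomain B) and (ii) the GPS autoproteolysis triad
(HL|T/S) is present — either localized through a reference column of a
supplied alignment or by a motif scan over the C-terminal third of
subdomain B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from gaingrn.structio import SSEAssignment, Structure

DEFAULT_KERNEL_WIDTH = 9
DEFAULT_EPS = 0.05
DEFAULT_MIN_BLOCK = 3


@dataclass
class ClassSignal:
    raw: np.ndarray        # int, values in {-1, 0, +1}
    smoothed: np.ndarray   # float, |s| <= 1
    kernel_width: int


@dataclass(frozen=True)
class SegmentBlock:
    kind: str   # "helical" | "strand"
    start: int  # 1-based inclusive
    end: int

    @property
    def span(self):
        return (self.start, self.end)

    def __len__(self):
        return self.end - self.start + 1


@dataclass
class GainDomain:
    """Outcome of detection on one structure."""

    structure: Structure
    valid: bool
    failure_reason: str = "none"  # no-subdomain-A | no-subdomain-B | no-GPS | none
    domain_span: Optional[tuple] = None
    subdomainA_span: Optional[tuple] = None
    subdomainB_span: Optional[tuple] = None
    gps: Optional[tuple] = None  # ordinals of (GPS.-2, GPS.-1, GPS.+1)
    gps_confidence: str = "none"  # canonical | degenerate | msa | none
    blocks: list = field(default_factory=list)
    group: Optional[str] = None


def sse_to_signal(sse: SSEAssignment) -> np.ndarray:
    """H -> +1, E -> -1, C -> 0."""
    if len(sse) == 0:
        raise ValueError("empty SSE assignment")
    lut = {"H": 1, "E": -1, "C": 0}
    return np.array([lut[c] for c in sse.classes], dtype=int)


def smooth_signal(raw: np.ndarray, kernel_width: int = DEFAULT_KERNEL_WIDTH) -> np.ndarray:
    """Same-length box-kernel convolution.

    Edge values are normalized over the truncated window so that a
    constant input stays constant (no zero-padding pull toward 0).
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if kernel_width % 2 == 0 or kernel_width < 1:
        raise ValueError("kernel width must be odd and positive")
    if kernel_width > n:
        raise ValueError("kernel wider than signal")
    kern = np.ones(kernel_width)
    num = np.convolve(raw, kern, mode="same")
    den = np.convolve(np.ones(n), kern, mode="same")
    return num / den


def find_blocks(smoothed: np.ndarray, eps: float = DEFAULT_EPS,
                min_block: int = DEFAULT_MIN_BLOCK) -> list[SegmentBlock]:
    """Maximal sign-constant runs of the smoothed signal.

    Positions with |s| < eps are separators; runs shorter than
    ``min_block`` are discarded.
    """
    s = np.asarray(smoothed, dtype=float)
    sign = np.where(s >= eps, 1, np.where(s <= -eps, -1, 0))
    blocks = []
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        if sign[i] != 0 and j - i >= min_block:
            kind = "helical" if sign[i] > 0 else "strand"
            blocks.append(SegmentBlock(kind, i + 1, j))
        i = j
    return blocks


def detect_subdomains(blocks: Sequence[SegmentBlock]):
    """Locate subdomain B (terminal strand run) and subdomain A.

    B is the contiguous run of strand blocks after the last helical block;
    A is the helical-block region with the greatest total helical residue
    count among regions N-terminal of B (tie -> the more C-terminal one).
    Returns ``(A_span or None, B_span or None)``.
    """
    strand_after = []
    last_helix_idx = -1
    for idx, b in enumerate(blocks):
        if b.kind == "helical":
            last_helix_idx = idx
    strand_after = [b for b in blocks[last_helix_idx + 1:] if b.kind == "strand"]
    if not strand_after:
        # no helices at all, or no strands after the last helix: B is the
        # terminal strand run only if the chain ends in strands
        strand_after = [b for b in blocks if b.kind == "strand"] if last_helix_idx < 0 else []
    if not strand_after:
        return (None, None)
    b_span = (strand_after[0].start, strand_after[-1].end)

    # helical regions: maximal runs of consecutive helical blocks N-terminal of B
    regions = []
    cur = []
    for b in blocks:
        if b.start >= b_span[0]:
            break
        if b.kind == "helical":
            cur.append(b)
        else:
            if cur:
                regions.append(cur)
            cur = []
    if cur:
        regions.append(cur)
    if not regions:
        return (None, b_span)
    best = max(regions, key=lambda reg: (sum(len(b) for b in reg), reg[-1].end))
    a_span = (best[0].start, best[-1].end)
    return (a_span, b_span)


# ---------------------------------------------------------------------------
# GPS localization


def _scan_motif(sequence: str, lo: int, hi: int, strict: bool):
    """Most C-terminal H-L-[TS] (strict) or x-L-[TS] match within [lo, hi]."""
    hit = None
    for i in range(lo, hi - 1):  # i = 1-based ordinal of the first triad residue
        a, b, c = sequence[i - 1], sequence[i], sequence[i + 1]
        if b == "L" and c in "TS" and (a == "H" or not strict):
            hit = (i, i + 1, i + 2)
    return hit


def locate_gps(sequence: str, b_span: Optional[tuple] = None,
               msa: Optional[dict] = None, seq_id: Optional[str] = None,
               gps_column: Optional[int] = None):
    """Find the GPS triad (GPS.-2, GPS.-1, GPS.+1) ordinals.

    MSA mode: ``msa`` maps sequence id -> aligned row; ``gps_column`` is
    the 1-based alignment column of the GPS.-1 residue. A sequence whose
    row is occupied at that column satisfies the GPS criterion; the triad
    is read off the neighboring columns (falling back to sequence
    neighbors across gaps). Fallback mode scans the C-terminal third of
    subdomain B for the canonical H-L-[T/S] motif, then for the degenerate
    x-L-[T/S]. Returns ``(ordinals, confidence)`` or ``(None, "none")``.
    """
    if msa is not None and gps_column is not None and seq_id is not None:
        row = msa.get(seq_id)
        if row is None:
            return (None, "none")
        col = gps_column - 1
        if col >= len(row) or row[col] == "-":
            return (None, "none")
        ordinal = len(row[:col + 1].replace("-", ""))
        if ordinal < 2 or ordinal >= len(sequence.replace("-", "")) :
            return (None, "none")
        return ((ordinal - 1, ordinal, ordinal + 1), "msa")

    if b_span is None:
        lo, hi = 1, len(sequence)
    else:
        third = (b_span[1] - b_span[0] + 1) // 3
        lo, hi = b_span[1] - third + 1, b_span[1]
    lo = max(lo, 2)
    hit = _scan_motif(sequence, lo - 1, hi, strict=True)
    if hit:
        return (hit, "canonical")
    hit = _scan_motif(sequence, lo - 1, hi, strict=False)
    if hit:
        return (hit, "degenerate")
    return (None, "none")


# ---------------------------------------------------------------------------


def _nterm_boundary(smoothed: np.ndarray, a_start: int, eps: float) -> int:
    """Domain N-boundary: signal decay N-terminal of subdomain A.

    Scanning N-ward from the subdomain A start, the first position where
    the smoothed helical signal has decayed below eps marks the end of the
    domain; the boundary is the position after it. Reaching the chain
    start without decay puts the boundary at 1.
    """
    for i in range(a_start - 1, 0, -1):
        if abs(smoothed[i - 1]) < eps:
            return i + 1
    return 1


def detect_gain(structure: Structure, sse: SSEAssignment,
                kernel_width: int = DEFAULT_KERNEL_WIDTH,
                eps: float = DEFAULT_EPS,
                min_block: int = DEFAULT_MIN_BLOCK,
                msa: Optional[dict] = None,
                gps_column: Optional[int] = None,
                group: Optional[str] = None) -> GainDomain:
    """Run the full detection pipeline on one structure.

    Validity requires both subdomains (criterion 1) and the GPS
    (criterion 2); the first missing piece is reported as
    ``failure_reason``.
    """
    if len(sse) != len(structure):
        raise ValueError("SSE assignment length does not match structure")
    raw = sse_to_signal(sse)
    smoothed = smooth_signal(raw, kernel_width)
    blocks = find_blocks(smoothed, eps, min_block)
    a_span, b_span = detect_subdomains(blocks)
    dom = GainDomain(structure, valid=False, blocks=blocks, group=group)
    dom.subdomainA_span = a_span
    dom.subdomainB_span = b_span
    if b_span is None:
        dom.failure_reason = "no-subdomain-B"
        return dom
    if a_span is None:
        dom.failure_reason = "no-subdomain-A"
        return dom
    gps, conf = locate_gps(structure.sequence, b_span, msa=msa,
                           seq_id=structure.id, gps_column=gps_column)
    dom.gps = gps
    dom.gps_confidence = conf
    if gps is None:
        dom.failure_reason = "no-GPS"
        return dom
    start = _nterm_boundary(smoothed, a_span[0], eps)
    dom.domain_span = (start, b_span[1])
    dom.valid = True
    return dom


def truncate_candidate(length: int, cterm_boundary: int, limit: int = 800):
    """Trim long candidate sequences before detection.

    Sequences longer than ``limit`` keep only the ``limit`` residues ending
    at the C-terminal boundary (the GAIN domain is expected a few hundred
    residues upstream of it); shorter sequences pass unchanged. Returns an
    inclusive 1-based span.
    """
    if not (1 <= cterm_boundary <= length):
        raise ValueError("C-terminal boundary out of range")
    if length <= limit:
        return (1, length)
    return (max(1, cterm_boundary - limit + 1), cterm_boundary)
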