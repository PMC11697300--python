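"""Rigid-body superposition and order-preserving pairwise alignment.

The pairwise aligner provides the residue-match + RMSD contract the GRN
pipeline needs: correspondences are seeded from secondary-structure block
pairing, then refined by alternating least-squares (Kabsch) superposition
with order-preserving dynamic-programming re-matching on the Calpha
distance matrix until the match set stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from gaingrn.structio import SSEAssignment, Structure, assign_sse_builtin

D_MATCH = 3.0        # Angstrom cutoff for a residue-residue match
MAX_ITER = 50
_SEED_MIN_BLOCK = 3  # minimum SSE-run length used for seeding


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AlignmentResult:
    matches: list            # [(ordinal_in_A, ordinal_in_B), ...] strictly increasing
    rmsd: float              # Angstrom over matched Calpha
    transform: RigidTransform
    coverage: float          # matched fraction of the shorter structure

    def match_dict(self) -> dict:
        return dict(self.matches)


@dataclass
class RMSDMatrix:
    ids: list
    values: np.ndarray  # symmetric, zero diagonal; np.inf marks incomparable pairs


def superpose_kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares superposition of P onto Q (Kabsch, via SVD).

    Returns ``(RigidTransform, rmsd)`` minimizing RMSD of R P + t vs Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("non-finite coordinates")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return RigidTransform(R, t), rmsd


# ---------------------------------------------------------------------------
# order-preserving matching


def _sse_runs(classes: str, lo: int, hi: int):
    """Runs of identical H/E class within [lo, hi] (1-based), len >= seed min."""
    runs = []
    i = lo
    while i <= hi:
        j = i
        while j <= hi and classes[j - 1] == classes[i - 1]:
            j += 1
        if classes[i - 1] in "HE" and j - i >= _SEED_MIN_BLOCK:
            runs.append((classes[i - 1], i, j - 1))
        i = j
    return runs


def _pair_runs_lcs(runs_a, runs_b):
    """Order-preserving LCS pairing of same-kind SSE runs (fallback)."""
    na, nb = len(runs_a), len(runs_b)
    F = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            same = runs_a[i - 1][0] == runs_b[j - 1][0]
            F[i, j] = max(F[i - 1, j], F[i, j - 1], F[i - 1, j - 1] + (1 if same else 0))
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if runs_a[i - 1][0] == runs_b[j - 1][0] and F[i, j] == F[i - 1, j - 1] + 1:
            pairs.append((runs_a[i - 1], runs_b[j - 1]))
            i, j = i - 1, j - 1
        elif F[i - 1, j] >= F[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


_PAIRING_CAP = 2000


def _enumerate_injections(runs_small, runs_big, cap=_PAIRING_CAP):
    """Order-preserving, kind-respecting injections of the smaller run list
    into the larger one (every small run matched)."""
    out = []

    def rec(i, j, cur):
        if len(out) >= cap:
            return
        if i == len(runs_small):
            out.append(list(cur))
            return
        if len(runs_small) - i > len(runs_big) - j:
            return
        if runs_small[i][0] == runs_big[j][0]:
            cur.append((runs_small[i], runs_big[j]))
            rec(i + 1, j + 1, cur)
            cur.pop()
        rec(i, j + 1, cur)

    rec(0, 0, [])
    return out


def _run_points(run, get_ca):
    _, s, e = run
    return [get_ca(s), get_ca((s + e) // 2), get_ca(e)]


def _best_pairing(runs_a, runs_b, ca_a, ca_b):
    """Pick the block pairing whose endpoints superpose best.

    All order-preserving same-kind pairings that match every block of the
    smaller structure are scored by the Kabsch RMSD of their block
    (start, center, end) Calpha triplets; the geometric best wins. With
    too many candidates (heavily fragmented SSE) the LCS pairing is used.
    """
    swap = len(runs_a) > len(runs_b)
    small, big = (runs_b, runs_a) if swap else (runs_a, runs_b)
    cands = _enumerate_injections(small, big)
    if not cands or len(cands) >= _PAIRING_CAP:
        pairs = _pair_runs_lcs(runs_a, runs_b)
        return pairs
    best, best_rmsd = None, np.inf
    for cand in cands:
        pairs = [(b, a) for a, b in cand] if swap else cand
        if len(pairs) < 2:
            best = best or pairs
            continue
        P = np.array([p for ra, _ in pairs for p in _run_points(ra, ca_a)])
        Q = np.array([q for _, rb in pairs for q in _run_points(rb, ca_b)])
        try:
            _, rmsd = superpose_kabsch(P, Q)
        except ValueError:
            continue
        if rmsd < best_rmsd:
            best, best_rmsd = pairs, rmsd
    return best or _pair_runs_lcs(runs_a, runs_b)


def _seed_matches(pairs):
    """Center-aligned residue pairs inside each paired block."""
    matches = []
    for (ka, sa, ea), (kb, sb, eb) in pairs:
        la, lb = ea - sa + 1, eb - sb + 1
        k = min(la, lb)
        oa = sa + (la - k) // 2
        ob = sb + (lb - k) // 2
        matches.extend((oa + m, ob + m) for m in range(k))
    return matches


def _dp_match(dists: np.ndarray, d_match: float):
    """Max-score strictly-increasing match set; score = d_match - d, d < d_match."""
    S = np.where(dists < d_match, d_match - dists, -np.inf)
    n, m = S.shape
    F = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + S[i - 1, :]
        cand = np.maximum(F[i - 1, 1:], diag)
        F[i, 1:] = np.maximum.accumulate(cand)
        # running max realizes the F[i, j-1] horizontal move (gap cost 0)
    matches = []
    i, j = n, m
    while i > 0 and j > 0:
        if F[i, j] == F[i - 1, j]:
            i -= 1
        elif F[i, j] == F[i, j - 1]:
            j -= 1
        else:
            matches.append((i, j))
            i, j = i - 1, j - 1
    return matches[::-1]


def align_pair(A: Structure, B: Structure,
               sse_a: Optional[SSEAssignment] = None,
               sse_b: Optional[SSEAssignment] = None,
               span_a: Optional[tuple] = None,
               span_b: Optional[tuple] = None,
               d_match: float = D_MATCH,
               max_iter: int = MAX_ITER) -> AlignmentResult:
    """Order-preserving pairwise structural alignment of A onto B.

    Optional inclusive ordinal spans restrict the alignment to a
    subdomain. SSE assignments default to the builtin dihedral assigner.
    Raises when the structures share no SSE blocks to seed from.
    """
    if sse_a is None:
        sse_a = assign_sse_builtin(A)
    if sse_b is None:
        sse_b = assign_sse_builtin(B)
    lo_a, hi_a = span_a if span_a else (1, len(A))
    lo_b, hi_b = span_b if span_b else (1, len(B))
    ords_a = [o for o in range(lo_a, hi_a + 1) if A[o].ca is not None]
    ords_b = [o for o in range(lo_b, hi_b + 1) if B[o].ca is not None]
    if len(ords_a) < 10 or len(ords_b) < 10:
        raise ValueError("need at least 10 Calpha residues on each side")
    Pa = A.ca_coords(ords_a)
    Pb = B.ca_coords(ords_b)
    idx_a = {o: i for i, o in enumerate(ords_a)}
    idx_b = {o: i for i, o in enumerate(ords_b)}

    runs_a = _sse_runs(sse_a.classes, lo_a, hi_a)
    runs_b = _sse_runs(sse_b.classes, lo_b, hi_b)

    def _ca_a(o):
        return A[o].ca if A[o].ca is not None else Pa[min(idx_a.values())]

    def _ca_b(o):
        return B[o].ca if B[o].ca is not None else Pb[min(idx_b.values())]

    pairs = _best_pairing(runs_a, runs_b, _ca_a, _ca_b)
    seed = [(a, b) for a, b in _seed_matches(pairs)
            if a in idx_a and b in idx_b]
    if len(seed) < 3:
        raise ValueError("no seed correspondence (structures share no SSE blocks)")

    matches = [(idx_a[a], idx_b[b]) for a, b in seed]
    transform = RigidTransform.identity()
    for _ in range(max_iter):
        ia = [m[0] for m in matches]
        ib = [m[1] for m in matches]
        transform, _ = superpose_kabsch(Pa[ia], Pb[ib])
        moved = transform.apply(Pa)
        dists = np.linalg.norm(moved[:, None, :] - Pb[None, :, :], axis=2)
        new = [(i - 1, j - 1) for i, j in _dp_match(dists, d_match)]
        if not new:
            break
        if new == matches:
            matches = new
            break
        matches = new

    ia = [m[0] for m in matches]
    ib = [m[1] for m in matches]
    transform, rmsd = superpose_kabsch(Pa[ia], Pb[ib])
    out = [(ords_a[i], ords_b[j]) for i, j in matches]
    coverage = len(out) / min(len(ords_a), len(ords_b))
    return AlignmentResult(out, rmsd, transform, coverage)


def rmsd_matrix(structures: Sequence[Structure],
                sses: Optional[Sequence[SSEAssignment]] = None,
                spans: Optional[Sequence[tuple]] = None,
                d_match: float = D_MATCH) -> RMSDMatrix:
    """Symmetric matrix of pairwise alignment RMSDs.

    ``spans[i]`` restricts structure i to a subdomain. Pairs that fail to
    align get the incomparable sentinel (inf), which downstream clustering
    excludes.
    """
    n = len(structures)
    if n < 2:
        raise ValueError("need at least 2 structures")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = align_pair(
                    structures[i], structures[j],
                    sse_a=sses[i] if sses else None,
                    sse_b=sses[j] if sses else None,
                    span_a=spans[i] if spans else None,
                    span_b=spans[j] if spans else None,
                    d_match=d_match,
                )
                vals[i, j] = vals[j, i] = res.rmsd
            except ValueError:
                vals[i, j] = vals[j, i] = np.inf
    return RMSDMatrix([s.id for s in structures], vals)
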