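"""Kabsch superposition, iterative pairwise alignment and RMSD matrices."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gaingrn.align3d import align_pair, rmsd_matrix, superpose_kabsch
from gaingrn.structio import Residue, Structure
from gaingrn.synthgain import (build_domain, perturb, preset_canonical,
                               preset_minimal_a)


def _random_rotation(rng):
    return Rotation.random(random_state=rng).as_matrix()


def _oracle_min_rmsd(P, Q, n_starts=40, seed=0):
    """Independent minimum-RMSD search over rotation vectors (no SVD)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((P @ R.T - Q) ** 2).sum() / len(P))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_kabsch_identity():
    rng = np.random.default_rng(0)
    P = rng.normal(size=(10, 3))
    tr, rmsd = superpose_kabsch(P, P)
    assert rmsd <= 1e-9
    np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-8)


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(12, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    Q = P @ R.T + np.array([5.0, 0.0, 0.0])
    tr, rmsd = superpose_kabsch(P, Q)
    assert rmsd <= 1e-9
    np.testing.assert_allclose(tr.rotation, R, atol=1e-8)
    np.testing.assert_allclose(tr.apply(P), Q, atol=1e-8)


def test_kabsch_orthonormal_proper():
    rng = np.random.default_rng(2)
    for k in range(5):
        P = rng.normal(size=(6, 3))
        Q = rng.normal(size=(6, 3))
        tr, _ = superpose_kabsch(P, Q)
        R = tr.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_kabsch_equals_rotation_search_oracle(seed):
    """SVD minimum matches an independent rotation-vector search to 1e-4."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(5, 3)) * 3
    Q = P.copy()
    Q[0] += rng.normal(size=3)  # displace one point ~1 A
    Q = Q @ _random_rotation(rng).T + rng.normal(size=3)
    _, rmsd = superpose_kabsch(P, Q)
    assert rmsd == pytest.approx(_oracle_min_rmsd(P, Q, seed=seed), abs=1e-4)


def test_kabsch_rmsd_invariant_under_rigid_motion():
    rng = np.random.default_rng(7)
    P = rng.normal(size=(20, 3))
    Q = P + rng.normal(scale=0.5, size=P.shape)
    _, base = superpose_kabsch(P, Q)
    for k in range(3):
        R = _random_rotation(rng)
        t = rng.normal(size=3) * 10
        _, r1 = superpose_kabsch(P @ R.T + t, Q)
        _, r2 = superpose_kabsch(P, Q @ R.T + t)
        assert r1 == pytest.approx(base, abs=1e-6)
        assert r2 == pytest.approx(base, abs=1e-6)


def test_kabsch_input_validation():
    with pytest.raises(ValueError):
        superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    bad = np.full((4, 3), np.nan)
    with pytest.raises(ValueError):
        superpose_kabsch(bad, bad)


# ---------------------------------------------------------------------------
# align_pair


def test_align_rigid_copy_matches_everything(canonical_domain):
    st = canonical_domain.structure
    rng = np.random.default_rng(0)
    R = _random_rotation(rng)
    copy = st.transformed(R, np.array([10.0, -4.0, 2.0]))
    res = align_pair(st, copy, sse_a=canonical_domain.sse_truth,
                     sse_b=canonical_domain.sse_truth)
    assert res.coverage == pytest.approx(1.0)
    assert res.rmsd <= 1e-6
    assert all(a == b for a, b in res.matches)


def test_align_with_deleted_loop_residues(canonical_domain):
    """Deleting loop residues leaves all segment residues matched."""
    dom = canonical_domain
    st = dom.structure
    h1_end = dom.segment_spans["H1"][1]
    removed = set(range(h1_end + 2, h1_end + 7))  # 5 residues inside h1h2
    kept = [r for r in st.residues if r.ordinal not in removed]
    renum = {r.ordinal: i + 1 for i, r in enumerate(kept)}
    edited = Structure("edit", "A", [
        Residue(renum[r.ordinal], r.author_number, r.aa1, r.heavy_atoms, r.ca)
        for r in kept])
    sse_edit = "".join(dom.sse_truth.classes[r.ordinal - 1] for r in kept)
    from gaingrn.structio import SSEAssignment
    res = align_pair(edited, st, sse_a=SSEAssignment(sse_edit, "truth"),
                     sse_b=dom.sse_truth)
    assert res.rmsd <= 1e-6
    back = {b: a for a, b in res.matches}
    for seg_id, (s, e) in dom.segment_spans.items():
        for o in range(s, e + 1):
            assert o in back, (seg_id, o)


def test_align_reversed_chain_fails_or_low_coverage(canonical_domain):
    dom = canonical_domain
    st = dom.structure
    n = len(st)
    rev = Structure("rev", "A", [
        Residue(n - r.ordinal + 1, r.author_number, r.aa1, r.heavy_atoms, r.ca)
        for r in reversed(st.residues)])
    from gaingrn.structio import SSEAssignment
    sse_rev = SSEAssignment(dom.sse_truth.classes[::-1], "truth")
    try:
        res = align_pair(st, rev, sse_a=dom.sse_truth, sse_b=sse_rev)
    except ValueError:
        return
    assert res.coverage < 0.5


def test_align_rmsd_symmetric(canonical_domain):
    dom = perturb(canonical_domain, 0.3, seed=5)
    a = align_pair(canonical_domain.structure, dom.structure,
                   sse_a=canonical_domain.sse_truth, sse_b=dom.sse_truth)
    b = align_pair(dom.structure, canonical_domain.structure,
                   sse_a=dom.sse_truth, sse_b=canonical_domain.sse_truth)
    assert a.rmsd == pytest.approx(b.rmsd, abs=1e-6)


def test_align_matches_strictly_monotonic(canonical_domain):
    dom = perturb(canonical_domain, 0.5, seed=9)
    res = align_pair(canonical_domain.structure, dom.structure,
                     sse_a=canonical_domain.sse_truth, sse_b=dom.sse_truth)
    a_side = [a for a, _ in res.matches]
    b_side = [b for _, b in res.matches]
    assert a_side == sorted(a_side) and len(set(a_side)) == len(a_side)
    assert b_side == sorted(b_side) and len(set(b_side)) == len(b_side)


def test_align_noise_rmsd_envelope(canonical_spec):
    """RMSD against a noisy copy tracks sigma*sqrt(3) (both-sided noise
    adds sqrt(2); Kabsch fitting removes a little)."""
    base = build_domain(canonical_spec, seed=2)
    sigma = 0.3
    ratios = []
    for seed in range(20):
        noisy = perturb(base, sigma, seed=seed)
        res = align_pair(base.structure, noisy.structure,
                         sse_a=base.sse_truth, sse_b=noisy.sse_truth)
        ratios.append(res.rmsd / (sigma * np.sqrt(3)))
    assert 0.8 <= np.mean(ratios) <= 1.2


# ---------------------------------------------------------------------------
# rmsd_matrix


def test_rmsd_matrix_of_rigid_copies(canonical_domain):
    st = canonical_domain.structure
    rng = np.random.default_rng(3)
    copies = [st]
    for k in range(2):
        copies.append(st.transformed(_random_rotation(rng), rng.normal(size=3)))
    sses = [canonical_domain.sse_truth] * 3
    M = rmsd_matrix(copies, sses=sses)
    np.testing.assert_allclose(M.values, 0.0, atol=1e-6)


def test_rmsd_matrix_symmetric_zero_diagonal(canonical_spec, minimal_a_spec):
    doms = [perturb(build_domain(canonical_spec, seed=s), 0.2, seed=s)
            for s in (1, 2)]
    doms += [perturb(build_domain(minimal_a_spec, seed=3), 0.2, seed=3)]
    M = rmsd_matrix([d.structure for d in doms],
                    sses=[d.sse_truth for d in doms])
    np.testing.assert_allclose(M.values, M.values.T)
    np.testing.assert_allclose(np.diag(M.values), 0.0)
    assert (M.values[np.triu_indices(3, 1)] >= 0).all()


def test_rmsd_matrix_groups_separate(canonical_spec, minimal_a_spec):
    """Within-architecture RMSD below between-architecture RMSD."""
    doms = [perturb(build_domain(canonical_spec, seed=s), 0.3, seed=s)
            for s in (1, 2, 3)]
    doms += [perturb(build_domain(minimal_a_spec, seed=s), 0.3, seed=10 + s)
             for s in (1, 2)]
    M = rmsd_matrix([d.structure for d in doms],
                    sses=[d.sse_truth for d in doms])
    within = [M.values[i, j] for i in range(3) for j in range(i + 1, 3)]
    within += [M.values[3, 4]]
    between = [M.values[i, j] for i in range(3) for j in (3, 4)]
    assert np.mean(within) < np.mean(between)
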