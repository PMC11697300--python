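"""GRN grammar, anchor/offset resolution, merged-segment splitting,
template-based assignment and ensemble conservation tables."""

import numpy as np
import pytest

from gaingrn.gaindetect import detect_gain
from gaingrn.grnindex import (GPS_INDICES, GRNLabel, GRNMap, HELIX_SEGMENTS,
                              LOOP_IDS, STRAND_SEGMENTS, all_labels,
                              assign_grn, conservation_table, parse_label,
                              resolve_offset, split_merged)
from gaingrn.structio import SSEAssignment
from gaingrn.synthgain import (SegmentPlan, build_domain,
                               make_registry_for_spec, perturb,
                               preset_canonical)


# ---------------------------------------------------------------------------
# grammar


def test_schema_counts():
    assert len(HELIX_SEGMENTS) == 6
    assert len(STRAND_SEGMENTS) == 14
    assert len(LOOP_IDS) == 21
    assert len(GPS_INDICES) == 3


@pytest.mark.parametrize("text,seg,idx", [
    ("H6.50", "H6", 50),
    ("S14.47", "S14", 47),
    ("GPS.-1", "GPS", -1),
    ("GPS.+1", "GPS", 1),
    ("S1.1", "S1", 1),
])
def test_parse_valid_labels(text, seg, idx):
    lab = parse_label(text)
    assert (lab.segment, lab.index) == (seg, idx)


@pytest.mark.parametrize("text", [
    "H9.50",      # only H1..H6 exist
    "S15.50",     # only S1..S14
    "H6.0",       # index range starts at 1
    "H6.100",     # and ends at 99
    "GPS.0",      # GPS has -2,-1,+1 only
    "GPS.1",      # +1 must be written with the sign
    "h6.50",      # segment ids are uppercase
    "H6-50",
    "H6.050",
])
def test_parse_rejects_malformed(text):
    with pytest.raises(ValueError):
        parse_label(text)


def test_grammar_round_trip_exhaustive():
    labels = all_labels()
    assert len(labels) == 6 * 99 + 14 * 99 + 3
    for lab in labels:
        assert parse_label(str(lab)) == lab


def test_loop_ids_lowercase_and_flanked():
    assert LOOP_IDS[0] == "h1h2" and LOOP_IDS[-1] == "s14tm1"
    assert all(l == l.lower() for l in LOOP_IDS)
    assert "s13gps" in LOOP_IDS and "gpss14" in LOOP_IDS


# ---------------------------------------------------------------------------
# offset resolution


def test_offset_three_nterminal_gives_47():
    # S14 anchor at template ordinal 80 unmatched; nearest match at 77
    matches = {75: 301, 76: 302, 77: 303}
    q0, idx0, off = resolve_offset(matches, anchor=80)
    assert (q0, idx0, off) == (303, 47, -3)


def test_offset_zero_when_anchor_matched():
    matches = {79: 310, 80: 311, 81: 312}
    q0, idx0, off = resolve_offset(matches, anchor=80)
    assert (q0, idx0, off) == (311, 50, 0)


def test_offset_tie_prefers_nterminal_side():
    matches = {78: 308, 82: 312}
    q0, idx0, off = resolve_offset(matches, anchor=80)
    assert (q0, idx0, off) == (308, 48, -2)


def test_offset_no_matches_errors():
    with pytest.raises(ValueError):
        resolve_offset({}, anchor=10)


# ---------------------------------------------------------------------------
# merged-segment splitting


def _phi_psi(n, phi=-63.0, psi=-42.0):
    return [phi] * n, [psi] * n


def test_split_on_coil_residue_excluded_from_both_halves():
    sse = SSEAssignment("H" * 10 + "C" + "H" * 10, "truth")
    phi, psi = _phi_psi(21)
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, "A" * 21, kind="H")
    assert dec.rule == "coil"
    assert dec.split_residue == 11


def test_split_on_dihedral_outlier_without_coil():
    sse = SSEAssignment("H" * 21, "truth")
    phi, psi = _phi_psi(21)
    phi[10] = -63.0 + 6 * 10.0  # 6 SD from the helical phi mean
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, "A" * 21, kind="H")
    assert dec.rule == "dihedral-outlier"
    assert dec.split_residue == 11


def test_split_on_proline_when_angles_clean():
    sse = SSEAssignment("H" * 21, "truth")
    phi, psi = _phi_psi(21)
    seq = "A" * 10 + "P" + "A" * 10
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, seq, kind="H")
    assert dec.rule == "pro-gly"
    assert dec.split_residue == 11


def test_split_priority_coil_beats_outlier_and_proline():
    sse = SSEAssignment("H" * 8 + "C" + "H" * 12, "truth")
    phi, psi = _phi_psi(21)
    phi[12] = 120.0
    seq = "A" * 14 + "P" + "A" * 6
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, seq, kind="H")
    assert dec.rule == "coil"
    assert dec.split_residue == 9


def test_split_manual_element_is_last_resort():
    sse = SSEAssignment("H" * 21, "truth")
    phi, psi = _phi_psi(21)
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, "A" * 21, kind="H",
                       manual_split=12)
    assert dec.rule == "manual"
    assert dec.split_residue == 12


def test_split_unresolvable_flagged():
    sse = SSEAssignment("H" * 21, "truth")
    phi, psi = _phi_psi(21)
    dec = split_merged((1, 21), 5, 16, sse, phi, psi, "A" * 21, kind="H")
    assert dec.rule == "unsplit"
    assert dec.split_residue is None


# ---------------------------------------------------------------------------
# assignment


def test_self_consistency_recovers_planted_map(
        canonical_domain, canonical_registry, detected_canonical):
    grn = assign_grn(detected_canonical, canonical_registry,
                     canonical_domain.sse_truth)
    truth = canonical_domain.grn_truth
    assert grn.labels == truth.labels
    grn.validate()


def test_noisy_recovery_at_least_95_percent(canonical_spec, canonical_registry):
    ok = tot = 0
    for seed in range(3):
        dom = perturb(build_domain(canonical_spec, seed=20 + seed), 0.3,
                      seed=20 + seed)
        det = detect_gain(dom.structure, dom.sse_truth, group="canonical")
        grn = assign_grn(det, canonical_registry, dom.sse_truth)
        truth = dom.grn_truth
        tot += len(truth.labels)
        ok += sum(grn.labels.get(o) == l for o, l in truth.labels.items())
    assert ok / tot >= 0.95


def test_missing_segment_emits_no_labels(canonical_spec, canonical_registry):
    segs = tuple(s for s in canonical_spec.segments if s.seg_id != "H5")
    spec = type(canonical_spec)("noH5", segs, loop_len=canonical_spec.loop_len)
    dom = build_domain(spec, seed=4)
    det = detect_gain(dom.structure, dom.sse_truth, group="canonical")
    grn = assign_grn(det, canonical_registry, dom.sse_truth)
    segments = {l.segment for l in grn.labels.values()}
    assert "H5" not in segments
    for other in ("H1", "H4", "H6", "S1", "S14", "GPS"):
        assert other in segments


def test_assignment_rigid_invariance(canonical_domain, canonical_registry,
                                     detected_canonical):
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(8)
    R = Rotation.random(random_state=rng).as_matrix()
    moved = canonical_domain.structure.transformed(R, rng.normal(size=3) * 20)
    det2 = detect_gain(moved, canonical_domain.sse_truth, group="canonical")
    g1 = assign_grn(detected_canonical, canonical_registry,
                    canonical_domain.sse_truth)
    g2 = assign_grn(det2, canonical_registry, canonical_domain.sse_truth)
    assert g1.labels == g2.labels
    assert g1.loops == g2.loops


def test_loop_membership_canonical(canonical_domain, canonical_registry,
                                   detected_canonical):
    grn = assign_grn(detected_canonical, canonical_registry,
                     canonical_domain.sse_truth)
    assert set(grn.loops.values()) <= set(LOOP_IDS)
    # a residue between H1 and H2 carries h1h2
    h1_end = canonical_domain.segment_spans["H1"][1]
    assert grn.loops[h1_end + 1] == "h1h2"
    assert grn.loops[len(canonical_domain.structure)] == "s14tm1"


def test_injectivity_violation_caught():
    m = GRNMap("x", labels={1: GRNLabel("H6", 50), 5: GRNLabel("H6", 50)})
    with pytest.raises(ValueError, match="assigned"):
        m.validate()


def test_contiguity_violation_caught():
    m = GRNMap("x", labels={1: GRNLabel("H6", 49), 2: GRNLabel("H6", 51)})
    with pytest.raises(ValueError, match="contiguous"):
        m.validate()


# ---------------------------------------------------------------------------
# conservation


def _map_with(labels):
    return GRNMap("m", labels={o: parse_label(l) for o, l in labels.items()})


def test_conservation_full_and_partial():
    maps, seqs = [], {}
    for k in range(4):
        m = GRNMap(f"m{k}")
        m.labels[1] = parse_label("S14.50")
        if k < 3:
            m.labels[2] = parse_label("H5.50")
        maps.append(m)
        seqs[f"m{k}"] = "LW"
    freq, occ = conservation_table(maps, seqs)
    assert freq.loc["S14.50", "L"] == pytest.approx(1.0)
    assert occ["H5"] == pytest.approx(0.75)


def test_conservation_planted_70_percent(canonical_spec, canonical_registry):
    """A 70%-conserved anchor residue shows frequency exactly 0.7."""
    anchor_aa = dict(canonical_spec.anchor_aa)
    maps, seqs = [], {}
    for k in range(10):
        aa = dict(anchor_aa)
        aa["S10"] = "W" if k < 7 else "C"
        spec = type(canonical_spec)("mix", canonical_spec.segments,
                                    loop_len=canonical_spec.loop_len,
                                    anchor_aa=aa)
        dom = build_domain(spec, seed=300 + k)
        det = detect_gain(dom.structure, dom.sse_truth, group="canonical")
        grn = assign_grn(det, canonical_registry, dom.sse_truth)
        maps.append(grn)
        seqs[grn.structure_id] = dom.structure.sequence
    freq, occ = conservation_table(maps, seqs)
    assert freq.loc["S10.50", "W"] == pytest.approx(0.7)
    assert freq.loc["S10.50", "C"] == pytest.approx(0.3)
    assert occ["S10"] == pytest.approx(1.0)
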