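"""Template selection, anchor derivation and validation.

A template is a consensus structure for one subdomain of one receptor
group, picked by agglomerative clustering of a pairwise-RMSD matrix over
a random sub-selection of the group (lowest-mean-RMSD member of the
largest cluster). Per-segment anchor (.50) residues are derived by
aligning every ensemble member onto the template, stacking the pairwise
residue matches into per-column tables, and taking the column that
maximizes occupancy x top-residue identity. Templates are then validated
against the ensemble by anchor occupancy and matched Calpha distance.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from gaingrn.align3d import RMSDMatrix, align_pair
from gaingrn.structio import SSEAssignment, Structure, read_structure, write_pdb

DEFAULT_LINKAGE = "average"
DEFAULT_K = 3
OCCUPANCY_FLAG_THRESHOLD = 0.5


@dataclass
class TemplateEntry:
    """A consensus structure with its segment spans and anchors."""

    id: str
    subdomain: str                  # "A" | "B"
    structure: Structure
    sse: SSEAssignment
    span: tuple                     # subdomain span within the template
    segments: dict                  # segment id -> (start, end) ordinals
    anchors: dict = field(default_factory=dict)  # segment id -> ordinal
    group: Optional[str] = None


@dataclass
class AnchorStats:
    """Per-segment template fit over an ensemble."""

    occupancy: dict        # segment id -> fraction matching the anchor
    mean_distance: dict    # segment id -> mean matched Calpha-Calpha distance (A)
    flagged: list = field(default_factory=list)  # below-threshold segments


class TemplateRegistry:
    """Holds templates, per-group defaults and manual overrides.

    Overrides support the curation moves the workflow needs: moving an
    anchor, adding an extra segment span, and removing a segment.
    """

    def __init__(self):
        self.templates: dict[str, TemplateEntry] = {}
        self.defaults: dict[str, dict] = {}   # group -> {"A": id, "B": id}
        self.overrides: dict = {"anchors": {}, "segments": {}, "drop_segments": {}}

    def add(self, entry: TemplateEntry, default_for: Optional[str] = None) -> None:
        self.templates[entry.id] = entry
        if default_for is not None:
            self.defaults.setdefault(default_for, {})[entry.subdomain] = entry.id

    def apply_overrides(self) -> None:
        for tid, moves in self.overrides.get("anchors", {}).items():
            if tid in self.templates:
                self.templates[tid].anchors.update(
                    {seg: int(o) for seg, o in moves.items()})
        for tid, segs in self.overrides.get("segments", {}).items():
            if tid in self.templates:
                self.templates[tid].segments.update(
                    {seg: tuple(span) for seg, span in segs.items()})
        for tid, segs in self.overrides.get("drop_segments", {}).items():
            if tid in self.templates:
                for seg in segs:
                    self.templates[tid].segments.pop(seg, None)
                    self.templates[tid].anchors.pop(seg, None)

    def resolve(self, group: Optional[str] = None,
                structure: Optional[Structure] = None,
                sse: Optional[SSEAssignment] = None):
        """Template pair (A, B) for a domain.

        A known group resolves through the default table; otherwise the
        domain is aligned to every template and the lowest-RMSD one per
        subdomain wins.
        """
        if group is not None and group in self.defaults:
            d = self.defaults[group]
            return (self.templates.get(d.get("A")), self.templates.get(d.get("B")))
        if structure is None:
            if len(self.defaults) == 1:
                d = next(iter(self.defaults.values()))
                return (self.templates.get(d.get("A")), self.templates.get(d.get("B")))
            raise ValueError("cannot resolve templates without a group or structure")
        best = {"A": (np.inf, None), "B": (np.inf, None)}
        for entry in self.templates.values():
            try:
                res = align_pair(structure, entry.structure, sse_a=sse,
                                 sse_b=entry.sse, span_b=entry.span)
            except ValueError:
                continue
            if res.rmsd < best[entry.subdomain][0]:
                best[entry.subdomain] = (res.rmsd, entry)
        return (best["A"][1], best["B"][1])

    # -- serialization ------------------------------------------------------

    def save(self, path: str | os.PathLike, structure_dir: Optional[str] = None) -> None:
        """Write the registry as JSON; template structures go to PDB files."""
        path = os.fspath(path)
        structure_dir = structure_dir or os.path.dirname(os.path.abspath(path))
        os.makedirs(structure_dir, exist_ok=True)
        payload = {"templates": [], "defaults": self.defaults,
                   "overrides": self.overrides}
        for entry in self.templates.values():
            pdb_path = os.path.join(structure_dir, f"{entry.id}.pdb")
            write_pdb(entry.structure, pdb_path)
            payload["templates"].append({
                "id": entry.id,
                "subdomain": entry.subdomain,
                "structure": os.path.relpath(pdb_path, os.path.dirname(os.path.abspath(path))),
                "chain": entry.structure.chain,
                "sse": entry.sse.classes,
                "span": list(entry.span),
                "segments": {k: list(v) for k, v in entry.segments.items()},
                "anchors": entry.anchors,
                "group": entry.group,
            })
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TemplateRegistry":
        path = os.fspath(path)
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            payload = json.load(fh)
        reg = cls()
        for t in payload["templates"]:
            spath = t["structure"]
            if not os.path.isabs(spath):
                spath = os.path.join(base, spath)
            structure = read_structure(spath, t.get("chain"))
            structure.id = t["id"]
            entry = TemplateEntry(
                id=t["id"], subdomain=t["subdomain"], structure=structure,
                sse=SSEAssignment(t["sse"], "truth"), span=tuple(t["span"]),
                segments={k: tuple(v) for k, v in t["segments"].items()},
                anchors={k: int(v) for k, v in t["anchors"].items()},
                group=t.get("group"),
            )
            reg.templates[entry.id] = entry
        reg.defaults = payload.get("defaults", {})
        reg.overrides = payload.get("overrides", reg.overrides)
        reg.apply_overrides()
        return reg


# ---------------------------------------------------------------------------
# selection


def subsample_groups(ids: Sequence[str], groups: Sequence[str],
                     per_group: int = 400, seed: int = 0) -> dict:
    """Reproducible uniform sample without replacement within each group.

    Groups smaller than ``per_group`` are kept whole. Returns
    ``group -> list of ids``.
    """
    rng = np.random.default_rng(seed)
    byg: dict[str, list] = {}
    for i, g in zip(ids, groups):
        byg.setdefault(g, []).append(i)
    if not byg:
        raise ValueError("no groups to sample from")
    out = {}
    for g in sorted(byg):
        members = sorted(byg[g])
        if not members:
            raise ValueError(f"empty group {g!r}")
        if len(members) <= per_group:
            out[g] = members
        else:
            pick = rng.choice(len(members), size=per_group, replace=False)
            out[g] = [members[k] for k in sorted(pick)]
    return out


def cluster_and_pick(matrix: RMSDMatrix, linkage: str = DEFAULT_LINKAGE,
                     k: int = DEFAULT_K):
    """Agglomerative clustering on an RMSD matrix; pick the template.

    Members with any incomparable (non-finite) entry are excluded. The
    representative is the member of the largest cluster with minimal mean
    RMSD to its co-members; all ties break to the lexicographically
    smallest id. Returns ``(labels: dict id -> cluster, representative id)``.
    """
    vals = np.asarray(matrix.values, dtype=float)
    ids = list(matrix.ids)
    keep = [i for i in range(len(ids)) if np.isfinite(vals[i]).all()]
    if len(keep) == 0:
        raise ValueError("all pairs incomparable")
    sub = vals[np.ix_(keep, keep)]
    kept_ids = [ids[i] for i in keep]
    k_eff = min(k, len(keep))
    if len(keep) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k_eff, metric="precomputed",
                                        linkage=linkage)
        labels = model.fit_predict(sub)
    label_map = dict(zip(kept_ids, (int(l) for l in labels)))
    # largest cluster; size tie -> cluster containing the smallest id
    sizes: dict[int, list] = {}
    for i, lab in zip(range(len(keep)), labels):
        sizes.setdefault(int(lab), []).append(i)
    best_cluster = sorted(
        sizes, key=lambda c: (-len(sizes[c]), min(kept_ids[i] for i in sizes[c])))[0]
    members = sizes[best_cluster]
    def mean_rmsd(i):
        others = [j for j in members if j != i]
        if not others:
            return 0.0
        return float(np.mean([sub[i, j] for j in others]))
    rep = sorted(members, key=lambda i: (mean_rmsd(i), kept_ids[i]))[0]
    return label_map, kept_ids[rep]


# ---------------------------------------------------------------------------
# anchors


def _match_columns(template: TemplateEntry, dataset, d_match: float = 3.0):
    """Align every member onto the template and stack the matches.

    ``dataset`` items need ``structure``, ``sse_truth``/``sse`` and a
    subdomain span. Returns ``columns``: template ordinal -> list of
    (member index, member ordinal, aa).
    """
    columns: dict[int, list] = {}
    aligns = []
    for mi, member in enumerate(dataset):
        st = member.structure
        sse = getattr(member, "sse_truth", None) or getattr(member, "sse", None)
        span = (member.subdomainA_span if template.subdomain == "A"
                else member.subdomainB_span)
        res = align_pair(st, template.structure, sse_a=sse, sse_b=template.sse,
                         span_a=span, span_b=template.span, d_match=d_match)
        aligns.append(res)
        for q, t in res.matches:
            columns.setdefault(t, []).append((mi, q, st[q].aa1))
    return columns, aligns


def derive_anchors(template: TemplateEntry, dataset, d_match: float = 3.0):
    """Set the anchor (.50) ordinal of every template segment.

    For each segment the anchor is the template column maximizing
    occupancy x top-residue fraction over the aligned ensemble (tie ->
    the most N-terminal column). Returns the per-column score table.
    """
    columns, _ = _match_columns(template, dataset, d_match)
    n = len(dataset)
    scores = {}
    for t, entries in columns.items():
        occ = len(entries) / n
        aas = [aa for _, _, aa in entries]
        top = max(aas.count(a) for a in set(aas)) / len(aas)
        scores[t] = occ * top
    anchors = {}
    for seg_id, (s, e) in template.segments.items():
        if seg_id == "GPS":
            continue
        cand = [t for t in range(s, e + 1) if t in scores]
        if not cand:
            raise ValueError(f"segment {seg_id}: no matched columns")
        anchors[seg_id] = max(cand, key=lambda t: (scores[t], -t))
    template.anchors = anchors
    return anchors, scores


def validate_template(template: TemplateEntry, dataset,
                      d_match: float = 3.0,
                      occupancy_threshold: float = OCCUPANCY_FLAG_THRESHOLD) -> AnchorStats:
    """Anchor occupancy and mean matched Calpha distance over an ensemble."""
    columns, aligns = _match_columns(template, dataset, d_match)
    n = len(dataset)
    occupancy, mean_distance, flagged = {}, {}, []
    for seg_id, anchor in template.anchors.items():
        entries = columns.get(anchor, [])
        occupancy[seg_id] = len(entries) / n
        dists = []
        t_ca = template.structure[anchor].ca
        for mi, q, _ in entries:
            st = dataset[mi].structure
            moved = aligns[mi].transform.apply(st[q].ca[None, :])[0]
            dists.append(float(np.linalg.norm(moved - t_ca)))
        mean_distance[seg_id] = float(np.mean(dists)) if dists else np.nan
        if occupancy[seg_id] < occupancy_threshold:
            flagged.append(seg_id)
    return AnchorStats(occupancy, mean_distance, flagged)
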