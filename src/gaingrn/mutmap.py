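"""Mutation mapping and cancer/variant enrichment over GRN positions.

Position-specific mutation records (UniProt coordinates) are reconciled
with structure numbering, assigned the GRN of their residue, optionally
filtered by SIFT/PolyPhen impact, counted per label, and scored with a
log2 pseudocount odds ratio contrasting cancer-associated mutations with
natural variants: positive scores mark cancer-enriched positions,
negative scores variant-enriched ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from gaingrn.grnindex import GRNMap
from gaingrn.structio import Structure

MUTATION_COLUMNS = ["protein", "pos", "ref", "alt", "source", "sift", "polyphen"]
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_COUNT_FLOOR = 3  # minimum c+v for ranking eligibility


@dataclass(frozen=True)
class MutationRecord:
    protein: str
    pos: int               # UniProt position, 1-based
    ref: str
    alt: str
    source: str            # "cancer" | "variant"
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref/alt must be single letters")


def read_mutations(path) -> list:
    """Flat CSV/TSV with columns protein,pos,ref,alt,source[,sift,polyphen]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    recs = []
    for _, row in df.iterrows():
        recs.append(MutationRecord(
            protein=str(row["protein"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]), source=str(row["source"]),
            sift=None if "sift" not in row or pd.isna(row.get("sift")) else float(row["sift"]),
            polyphen=None if "polyphen" not in row or pd.isna(row.get("polyphen")) else float(row["polyphen"]),
        ))
    return recs


def reconcile_numbering(grnmap: GRNMap, structure: Structure,
                        offset: Optional[int] = None,
                        offset_table: Optional[Sequence] = None) -> dict:
    """Express the GRN map in UniProt coordinates.

    ``offset`` is the constant shift UniProt = author_number + offset; an
    ``offset_table`` of (author_lo, author_hi, offset) ranges handles
    structures with inconsistent numbering. Returns UniProt position ->
    ("structured", label) | ("loop", loop id).
    """
    if offset is None and offset_table is None:
        offset = 0

    def to_uniprot(author: int) -> Optional[int]:
        if offset is not None:
            return author + offset
        for lo, hi, off in offset_table:
            if lo <= author <= hi:
                return author + off
        return None

    out = {}
    for o, lab in grnmap.labels.items():
        u = to_uniprot(structure[o].author_number)
        if u is None:
            continue
        if u in out:
            raise ValueError(f"inconsistent offsets: UniProt {u} hit twice")
        out[u] = ("structured", lab)
    for o, lid in grnmap.loops.items():
        u = to_uniprot(structure[o].author_number)
        if u is None or u in out:
            continue
        out[u] = ("loop", lid)
    return out


def map_mutations(records: Sequence[MutationRecord], position_index: dict):
    """Assign each record a GRN label, a loop id, or "outside".

    Returns ``(DataFrame, tallies)``; tallies report the structured /
    loop / outside classes separately and always sum to the input count.
    """
    rows = []
    tallies = {"structured": 0, "loop": 0, "outside": 0}
    for r in records:
        hit = position_index.get(r.pos)
        if hit is None:
            cls, lab = "outside", ""
        else:
            cls, lab = hit[0], str(hit[1])
        tallies[cls] += 1
        rows.append({"protein": r.protein, "pos": r.pos, "ref": r.ref,
                     "alt": r.alt, "source": r.source, "class": cls,
                     "grn_label": lab if cls == "structured" else "",
                     "loop": lab if cls == "loop" else ""})
    return pd.DataFrame(rows), tallies


def filter_by_impact(records: Sequence[MutationRecord],
                     sift_max: Optional[float] = None,
                     polyphen_min: Optional[float] = None):
    """Keep records passing the requested impact thresholds.

    A record missing a requested score is dropped and counted under
    "missing-score". Returns ``(kept, tallies)``.
    """
    for thr in (sift_max, polyphen_min):
        if thr is not None and not (0.0 <= thr <= 1.0):
            raise ValueError("impact thresholds must lie in [0, 1]")
    kept, missing, failed = [], 0, 0
    for r in records:
        if sift_max is not None:
            if r.sift is None:
                missing += 1
                continue
            if r.sift > sift_max:
                failed += 1
                continue
        if polyphen_min is not None:
            if r.polyphen is None:
                missing += 1
                continue
            if r.polyphen < polyphen_min:
                failed += 1
                continue
        kept.append(r)
    return kept, {"kept": len(kept), "missing-score": missing, "failed": failed}


def count_positions(mapped: pd.DataFrame) -> dict:
    """Per-GRN-label (cancer, variant) counts from mapped structured records."""
    counts: dict = {}
    sub = mapped[mapped["class"] == "structured"]
    for _, row in sub.iterrows():
        c, v = counts.get(row["grn_label"], (0, 0))
        if row["source"] == "cancer":
            c += 1
        else:
            v += 1
        counts[row["grn_label"]] = (c, v)
    return counts


def enrichment_score(c: int, v: int, C: int, V: int, n_labels: int,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 pseudocount odds ratio of cancer vs variant proportions.

    score = log2((c+p)/(C+pN)) - log2((v+p)/(V+pN)). Positive marks
    cancer enrichment; the variant-enrichment score is its negative. The
    formula is isolated here so an alternative normalization can be
    swapped in one place.
    """
    p = pseudocount
    return (math.log2((c + p) / (C + p * n_labels))
            - math.log2((v + p) / (V + p * n_labels)))


def enrichment_scores(counts: dict, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      count_floor: int = DEFAULT_COUNT_FLOOR,
                      n_labels: Optional[int] = None) -> pd.DataFrame:
    """Score and rank every counted GRN position.

    ``n_labels`` defaults to the number of counted labels. Labels with
    c + v below ``count_floor`` keep their score but are marked
    ineligible for ranking (mirroring the exclusion of sparsely covered
    segments). Rows are ranked by score descending, ties broken by label
    string.
    """
    if not counts:
        raise ValueError("no counts")
    C = sum(c for c, _ in counts.values())
    V = sum(v for _, v in counts.values())
    if C + V == 0:
        raise ValueError("zero totals on both sides")
    N = n_labels if n_labels is not None else len(counts)
    rows = []
    for label, (c, v) in counts.items():
        rows.append({
            "label": label, "c": c, "v": v,
            "score": enrichment_score(c, v, C, V, N, pseudocount),
            "eligible": (c + v) >= count_floor,
        })
    df = pd.DataFrame(rows).sort_values(
        ["score", "label"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = 0
    elig = df["eligible"]
    df.loc[elig, "rank"] = range(1, int(elig.sum()) + 1)
    return df


def top_enriched(rows: pd.DataFrame, n: int = 10,
                 exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Top-n eligible positions by score, with whole segments excludable."""
    def seg(label: str) -> str:
        return label.split(".")[0]
    sub = rows[rows["eligible"] & ~rows["label"].map(seg).isin(set(exclude))]
    sub = sub.sort_values(["score", "label"], ascending=[False, True])
    return sub.head(n).reset_index(drop=True)
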