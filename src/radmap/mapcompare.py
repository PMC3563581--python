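"""Map comparison: sex span ratios, fragment-map merging, cross-species tags.

Male and female maps of one family share only their AB x AB markers, so
map totals are not directly comparable; instead the distance between the
most proximal and most distal *shared* markers within each paired group is
compared (female:male span ratio).  Small fragment maps from additional
families are merged where two or more markers overlap.  Tag catalogs from
two species are matched by ungapped fixed-length comparison: full-length
with at most one mismatch for unmapped loci, overlap >= 56 nt with at most
four mismatches for mapped loci, both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqs
from .linkmap import GeneticMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Female : male span ratios


def span_ratio_table(spans: pd.DataFrame) -> pd.DataFrame:
    """Ratios and totals from per-group female/male spans (cM).

    ``spans`` needs columns ``group``, ``female_cM``, ``male_cM``.  Appends
    a ``Total`` row with column sums and the ratio of the totals.
    """
    out = spans.copy()
    out["ratio"] = out["female_cM"] / out["male_cM"]
    total = pd.DataFrame(
        [
            {
                "group": "Total",
                "female_cM": out["female_cM"].sum(),
                "male_cM": out["male_cM"].sum(),
                "ratio": out["female_cM"].sum() / out["male_cM"].sum(),
            }
        ]
    )
    return pd.concat([out, total], ignore_index=True)


def _positions(genetic_map: GeneticMap) -> dict[str, tuple[str, float]]:
    pos = {}
    for g in genetic_map.groups:
        for rep, p in zip(g.markers, g.positions):
            for m in g.members.get(rep, [rep]):
                pos[m] = (g.group_id, float(p))
    return pos


def pair_groups(female_map: GeneticMap, male_map: GeneticMap) -> list[tuple[str, str]]:
    """Pair female/male groups by majority vote of their shared markers."""
    fpos = _positions(female_map)
    mpos = _positions(male_map)
    votes: dict[tuple[str, str], int] = {}
    for marker, (fg, _) in fpos.items():
        if marker in mpos:
            key = (fg, mpos[marker][0])
            votes[key] = votes.get(key, 0) + 1
    pairs = []
    used_f, used_m = set(), set()
    for (fg, mg), _ in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0])):
        if fg not in used_f and mg not in used_m:
            pairs.append((fg, mg))
            used_f.add(fg)
            used_m.add(mg)
    return sorted(pairs)


def _map_frame(genetic_map: GeneticMap) -> pd.DataFrame:
    rows = [
        {"marker": m, "group": grp, "position_cM": p}
        for m, (grp, p) in _positions(genetic_map).items()
    ]
    return pd.DataFrame(rows, columns=["marker", "group", "position_cM"])


def shared_span_ratio(female_map: GeneticMap, male_map: GeneticMap) -> pd.DataFrame:
    """Per paired group, the span between first and last shared markers.

    Groups are paired by majority vote of shared markers; pairs with fewer
    than two shared markers are skipped with a warning.  Returns the ratio
    table with a Total row.
    """
    return shared_span_ratio_from_frames(_map_frame(female_map), _map_frame(male_map))


def shared_span_ratio_from_frames(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Span-ratio table from exported map tables (marker, group, position_cM)."""
    fpos = {r.marker: (r.group, float(r.position_cM)) for r in female.itertuples()}
    mpos = {r.marker: (r.group, float(r.position_cM)) for r in male.itertuples()}
    votes: dict[tuple[str, str], int] = {}
    for marker, (fg, _) in fpos.items():
        if marker in mpos:
            key = (fg, mpos[marker][0])
            votes[key] = votes.get(key, 0) + 1
    rows = []
    used_f, used_m = set(), set()
    for (fg, mg), _ in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0])):
        if fg in used_f or mg in used_m:
            continue
        used_f.add(fg)
        used_m.add(mg)
        shared = [
            m for m in fpos if fpos[m][0] == fg and m in mpos and mpos[m][0] == mg
        ]
        if len(shared) < 2:
            logger.warning(
                "group pair (%s, %s): fewer than 2 shared markers, skipped", fg, mg
            )
            continue
        f = [fpos[m][1] for m in shared]
        m_ = [mpos[m][1] for m in shared]
        rows.append(
            {
                "group": f"{fg}/{mg}",
                "n_shared": len(shared),
                "female_cM": max(f) - min(f),
                "male_cM": max(m_) - min(m_),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["group", "n_shared", "female_cM", "male_cM", "ratio"])
    return span_ratio_table(pd.DataFrame(rows).sort_values("group").reset_index(drop=True))


# ---------------------------------------------------------------------------
# Fragment-map merging across families


def _orient(fragment: list[str], anchor_order: dict[str, int]) -> list[str] | None:
    """Orient ``fragment`` so shared markers run in anchor order; None on conflict."""
    shared = [m for m in fragment if m in anchor_order]
    ranks = [anchor_order[m] for m in shared]
    if ranks == sorted(ranks):
        return fragment
    if ranks == sorted(ranks, reverse=True):
        return fragment[::-1]
    return None


def _merge_two(anchor: list[str], other: list[str]) -> list[str] | None:
    """Merge one fragment into an anchor sharing >= 2 markers, or None."""
    anchor_order = {m: i for i, m in enumerate(anchor)}
    oriented = _orient(other, anchor_order)
    if oriented is None:
        return None
    merged = list(anchor)
    # insert exclusive markers after their nearest preceding shared neighbour
    last_anchor_idx = -1
    pending: list[str] = []
    inserts: list[tuple[int, list[str]]] = []
    for m in oriented:
        if m in anchor_order:
            if pending:
                inserts.append((last_anchor_idx, pending))
                pending = []
            last_anchor_idx = anchor_order[m]
        else:
            pending.append(m)
    if pending:
        inserts.append((last_anchor_idx, pending))
    for idx, block in sorted(inserts, key=lambda t: t[0], reverse=True):
        pos = merged.index(anchor[idx]) + 1 if idx >= 0 else 0
        merged[pos:pos] = block
    return merged


def merge_fragment_maps(fragments: list[list[str]]) -> tuple[list[list[str]], list[tuple]]:
    """Iteratively union fragments sharing two or more markers.

    The larger fragment anchors the merged order; exclusive markers are
    inserted next to their shared neighbours.  Incompatible shared-marker
    orders leave both fragments unmerged and log the conflict.  The result
    is independent of input order (fragments are processed sorted).
    """
    pool = sorted((list(f) for f in fragments), key=lambda f: (-len(f), f))
    conflicts: list[tuple] = []
    merged_any = True
    while merged_any:
        merged_any = False
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                shared = set(pool[a]) & set(pool[b])
                if len(shared) < 2:
                    continue
                anchor, other = pool[a], pool[b]
                if len(other) > len(anchor):
                    anchor, other = other, anchor
                result = _merge_two(anchor, other)
                if result is None:
                    key = (tuple(pool[a]), tuple(pool[b]))
                    if key not in conflicts:
                        conflicts.append(key)
                        logger.warning(
                            "fragment order conflict, left unmerged: %s vs %s",
                            pool[a], pool[b],
                        )
                    continue
                pool.pop(b)
                pool.pop(a)
                pool.append(result)
                pool.sort(key=lambda f: (-len(f), f))
                merged_any = True
                break
            if merged_any:
                break
    return pool, conflicts


# ---------------------------------------------------------------------------
# Cross-species tag matching


@dataclass
class TagCatalogView:
    """Tags (ids + sequences) with optional linkage-group assignment."""

    ids: list[str]
    tags: np.ndarray                     # (n, 59) uint8
    linkage_group: dict[str, str] | None = None

    @classmethod
    def from_sequences(cls, mapping: dict[str, str],
                       linkage_group: dict[str, str] | None = None):
        ids = sorted(mapping)
        return cls(
            ids=ids,
            tags=seqs.encode_many([mapping[i] for i in ids]),
            linkage_group=linkage_group,
        )

    @classmethod
    def from_fasta(cls, path, linkage_group: dict[str, str] | None = None):
        from Bio import SeqIO

        mapping = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls.from_sequences(mapping, linkage_group)


def match_tags(query: TagCatalogView, subject: TagCatalogView,
               mode: str = "unmapped", max_mismatches_unmapped: int = 1,
               max_mismatches_mapped: int = 4, min_overlap: int = 56) -> pd.DataFrame:
    """Ungapped tag matching between two catalogs, both strands.

    mode='unmapped': accept full-length (59 nt) comparisons with at most
    one mismatch.  mode='mapped': accept any contiguous offset overlap of
    at least ``min_overlap`` nt with at most four mismatches.  The best
    match per query is kept (fewest mismatches, then longest overlap, then
    subject id).
    """
    if mode not in ("unmapped", "mapped"):
        raise ValueError("mode must be 'unmapped' or 'mapped'")
    tag_len = query.tags.shape[1]
    if mode == "unmapped":
        offsets = [0]
        max_mm = max_mismatches_unmapped
    else:
        max_shift = tag_len - min_overlap
        offsets = list(range(-max_shift, max_shift + 1))
        max_mm = max_mismatches_mapped

    subj_strands = [("+", subject.tags), ("-", seqs.revcomp_rows(subject.tags))]
    best: dict[int, tuple] = {}  # query idx -> (mm, -overlap, subject id, strand)
    for strand, subj in subj_strands:
        for off in offsets:
            if off >= 0:
                q_slice = slice(off, tag_len)
                s_slice = slice(0, tag_len - off)
            else:
                q_slice = slice(0, tag_len + off)
                s_slice = slice(-off, tag_len)
            overlap = tag_len - abs(off)
            d = seqs.hamming_matrix(
                np.ascontiguousarray(query.tags[:, q_slice]),
                np.ascontiguousarray(subj[:, s_slice]),
            )
            qi, sj = np.nonzero(d <= max_mm)
            for q, s in zip(qi, sj):
                key = (int(d[q, s]), -overlap, subject.ids[s], strand)
                if q not in best or key < best[q]:
                    best[int(q)] = key
    rows = []
    for q in sorted(best):
        mm, neg_overlap, sid, strand = best[q]
        qid = query.ids[q]
        rows.append(
            {
                "query_id": qid,
                "subject_id": sid,
                "overlap": -neg_overlap,
                "mismatches": mm,
                "strand": strand,
                "gap": False,
                "accepted": True,
                "query_lg": (query.linkage_group or {}).get(qid),
                "subject_lg": (subject.linkage_group or {}).get(sid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["query_id", "subject_id", "overlap", "mismatches", "strand",
                 "gap", "accepted", "query_lg", "subject_lg"],
    )


def synteny_table(matches: pd.DataFrame) -> pd.DataFrame:
    """Counts of accepted matches per (query LG, subject LG) pair."""
    mapped = matches[
        matches["accepted"]
        & matches["query_lg"].notna()
        & matches["subject_lg"].notna()
    ]
    if mapped.empty:
        return pd.DataFrame(columns=["query_lg", "subject_lg", "n_hits"])
    out = (
        mapped.groupby(["query_lg", "subject_lg"]).size().rename("n_hits").reset_index()
    )
    return out.sort_values(["query_lg", "subject_lg"]).reset_index(drop=True)
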