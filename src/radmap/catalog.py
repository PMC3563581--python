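"""Parental tag catalog: unique-tag counting, locus clustering, paralog filter.

SNP discovery uses only the two parents.  Unique 59-nt tags are counted per
parent, tags seen fewer than ``min_count`` times in a parent are not trusted
for that parent (sequencing-error singletons form a sharp low-count peak),
and surviving tags are joined into candidate loci by single-linkage
clustering at Hamming distance <= ``max_mismatches`` (tags are fixed-length,
so no indels).  Clusters with more than two retained sequences overall, or
more than two in either parent, look like collapsed paralogs and are
dropped; retained two-allele clusters polymorphic within at least one parent
are the mappable putative SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import seqs

CLASS_MONO = "monomorphic"
CLASS_FIXED = "fixed_difference"
CLASS_POLY_ONE = "poly_one_parent"
CLASS_POLY_BOTH = "poly_both_parents"

STATUS_RETAINED = "retained"
STATUS_PARALOG = "dropped_paralog"
STATUS_LOW_COUNT = "dropped_low_count"
STATUS_UNSHARED = "dropped_unshared"

MAPPABLE_CLASSES = (CLASS_POLY_ONE, CLASS_POLY_BOTH)


def count_unique_tags(tags_parent1, tags_parent2, counts_parent1=None,
                      counts_parent2=None) -> pd.DataFrame:
    """Tabulate distinct tag sequences with per-parent occurrence counts.

    Inputs may be (n, 59) uint8 arrays of raw tags, or unique-tag arrays
    with matching count vectors (as produced by read processing).
    """
    def normalise(tags, counts):
        if isinstance(tags, np.ndarray) and tags.ndim == 2:
            arr = tags
        else:
            arr = seqs.encode_many(list(tags))
        if counts is None:
            counts = np.ones(arr.shape[0], dtype=np.int64)
        return arr, np.asarray(counts, dtype=np.int64)

    arr1, c1 = normalise(tags_parent1, counts_parent1)
    arr2, c2 = normalise(tags_parent2, counts_parent2)
    if arr1.shape[0] + arr2.shape[0] == 0:
        return pd.DataFrame(
            {"tag": pd.Series(dtype=str),
             "count_parent1": pd.Series(dtype=np.int64),
             "count_parent2": pd.Series(dtype=np.int64)}
        )
    width = max(arr1.shape[1] if arr1.size else 0, arr2.shape[1] if arr2.size else 0)
    stacked = np.vstack([a.reshape(-1, width) for a in (arr1, arr2)])
    origin1 = np.concatenate([np.ones(arr1.shape[0], bool), np.zeros(arr2.shape[0], bool)])
    weights = np.concatenate([c1, c2])
    uniq, inverse, _ = seqs.unique_rows(stacked)
    n = uniq.shape[0]
    out1 = np.zeros(n, dtype=np.int64)
    out2 = np.zeros(n, dtype=np.int64)
    np.add.at(out1, inverse[origin1], weights[origin1])
    np.add.at(out2, inverse[~origin1], weights[~origin1])
    return pd.DataFrame(
        {"tag": seqs.decode_rows(uniq), "count_parent1": out1, "count_parent2": out2}
    )


def tag_count_histogram(table: pd.DataFrame) -> pd.DataFrame:
    """Frequency distribution of per-tag occurrence counts, per parent.

    The low-count sequencing-error peak (counts 1-5) is visible as a sharp
    spike at the left of this histogram; the diploid coverage peak sits
    near the mean per-allele depth.
    """
    rows = {}
    for parent in ("count_parent1", "count_parent2"):
        counts = table.loc[table[parent] > 0, parent].value_counts().sort_index()
        rows[parent.replace("count_", "n_tags_")] = counts
    out = pd.DataFrame(rows).fillna(0).astype(int)
    out.index.name = "occurrences"
    return out.reset_index()


def low_count_filter(table: pd.DataFrame, min_count: int = 6) -> pd.DataFrame:
    """Mark per-parent retention; drop tags below threshold in both parents.

    A tag is trusted for a parent iff its count in that parent is at least
    ``min_count`` (the low-count error peak spans counts 1-5 at default).
    """
    out = table.copy()
    out["retained_parent1"] = out["count_parent1"] >= min_count
    out["retained_parent2"] = out["count_parent2"] >= min_count
    return out[out["retained_parent1"] | out["retained_parent2"]].reset_index(drop=True)


@dataclass
class Catalog:
    """Clustered candidate loci with classification and filter status."""

    loci: pd.DataFrame       # locus_id, allele1, allele2, snp_position, class_, status, ...
    members: pd.DataFrame    # tag, locus_id, count_parent1/2, retained_parent1/2

    def retained(self) -> pd.DataFrame:
        return self.loci[self.loci["status"] == STATUS_RETAINED]

    def mappable(self) -> pd.DataFrame:
        r = self.retained()
        return r[r["class"].isin(MAPPABLE_CLASSES)]

    def class_counts(self) -> pd.Series:
        return self.retained()["class"].value_counts()

    def snp_position_histogram(self) -> pd.Series:
        """Counts of SNP offset within the tag; flat on clean data."""
        m = self.mappable()
        return m["snp_position"].value_counts().sort_index()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.loci.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        self.snp_position_histogram().rename("count").to_csv(
            outdir / "snp_position_hist.tsv", sep="\t"
        )


def _parent_genotype(has1: bool, has2: bool, n_alleles: int):
    if n_alleles == 1:
        return "AA" if has1 else None
    if has1 and has2:
        return "AB"
    if has1:
        return "AA"
    if has2:
        return "BB"
    return None


def cluster_loci(filtered: pd.DataFrame, max_mismatches: int = 3) -> Catalog:
    """Single-linkage Hamming clustering of retained tags into loci.

    Within a cluster the two highest-count sequences overall become the
    locus alleles; allele1 is the lexicographically smaller (the reference
    allele — a deterministic tie-break so runs are reproducible).
    """
    if filtered.empty:
        loci = pd.DataFrame(
            columns=["locus_id", "allele1", "allele2", "snp_position", "class",
                     "status", "parent1", "parent2", "n_members"]
        )
        return Catalog(loci=loci, members=filtered.assign(locus_id=pd.Series(dtype=str)))

    arr = seqs.encode_many(list(filtered["tag"]))
    n = arr.shape[0]
    rows, cols = [], []
    chunk = 1024
    for start in range(0, n, chunk):
        d = seqs.hamming_matrix(arr[start : start + chunk], arr)
        r, c = np.nonzero(d <= max_mismatches)
        rows.append(r + start)
        cols.append(c)
    graph = coo_matrix(
        (np.ones(sum(len(r) for r in rows), dtype=np.int8),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    n_comp, labels = connected_components(graph, directed=False)

    members = filtered.copy()
    total = members["count_parent1"].to_numpy() + members["count_parent2"].to_numpy()
    tags = members["tag"].to_numpy()

    records = []
    locus_of_cluster = {}
    # deterministic locus order: by lexicographically smallest member tag
    cluster_order = sorted(range(n_comp), key=lambda c: tags[labels == c].min())
    for new_id, c in enumerate(cluster_order):
        idx = np.flatnonzero(labels == c)
        locus_id = f"L{new_id + 1:06d}"
        locus_of_cluster[c] = locus_id
        sub_tags = tags[idx]
        sub_total = total[idx]
        r1 = members["retained_parent1"].to_numpy()[idx]
        r2 = members["retained_parent2"].to_numpy()[idx]
        n_members = len(idx)
        n_p1 = int(r1.sum())
        n_p2 = int(r2.sum())

        # paralog screen: more than 2 sequences overall or in either parent
        if n_members > 2 or n_p1 > 2 or n_p2 > 2:
            status = STATUS_PARALOG
        elif n_p1 == 0 or n_p2 == 0:
            status = STATUS_UNSHARED
        else:
            status = STATUS_RETAINED

        # alleles: two highest-count sequences; ties broken lexicographically
        pick = sorted(range(n_members), key=lambda i: (-sub_total[i], sub_tags[i]))[:2]
        alleles = sorted(sub_tags[i] for i in pick)
        allele1 = alleles[0]
        allele2 = alleles[1] if len(alleles) > 1 else None

        snp_position = -1
        if allele2 is not None:
            diff = [k for k, (x, y) in enumerate(zip(allele1, allele2)) if x != y]
            snp_position = diff[0] if diff else -1

        if allele2 is None:
            class_ = CLASS_MONO
            p1 = "AA" if n_p1 else None
            p2 = "AA" if n_p2 else None
        else:
            a1_idx = list(sub_tags).index(allele1)
            a2_idx = list(sub_tags).index(allele2)
            p1 = _parent_genotype(bool(r1[a1_idx]), bool(r1[a2_idx]), 2)
            p2 = _parent_genotype(bool(r2[a1_idx]), bool(r2[a2_idx]), 2)
            het1, het2 = p1 == "AB", p2 == "AB"
            if het1 and het2:
                class_ = CLASS_POLY_BOTH
            elif het1 or het2:
                class_ = CLASS_POLY_ONE
            elif p1 and p2 and p1 != p2:
                class_ = CLASS_FIXED
            else:
                class_ = CLASS_MONO
        records.append(
            {
                "locus_id": locus_id,
                "allele1": allele1,
                "allele2": allele2,
                "snp_position": snp_position,
                "class": class_,
                "status": status,
                "parent1": p1,
                "parent2": p2,
                "n_members": n_members,
            }
        )
    members["locus_id"] = [locus_of_cluster[c] for c in labels]
    loci = pd.DataFrame.from_records(records).sort_values("locus_id").reset_index(drop=True)
    return Catalog(loci=loci, members=members)


def paralog_filter(catalog: Catalog) -> Catalog:
    """Re-apply the paralog rule (idempotent; clustering already applies it)."""
    loci = catalog.loci.copy()
    bad = loci["n_members"] > 2
    loci.loc[bad, "status"] = STATUS_PARALOG
    return Catalog(loci=loci, members=catalog.members)


def build_catalog(tags_parent1, tags_parent2, counts_parent1=None,
                  counts_parent2=None, min_count: int = 6,
                  max_mismatches: int = 3) -> Catalog:
    """Count -> low-count filter -> cluster -> paralog filter."""
    table = count_unique_tags(
        tags_parent1, tags_parent2, counts_parent1, counts_parent2
    )
    filtered = low_count_filter(table, min_count=min_count)
    return paralog_filter(cluster_loci(filtered, max_mismatches=max_mismatches))


def export_snp_reference(catalog: Catalog, path) -> int:
    """Write mappable two-allele loci as a FASTA reference (2 records/locus)."""
    import warnings

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    loci = catalog.mappable()
    records = []
    for _, row in loci.iterrows():
        records.append(
            SeqRecord(Seq(row["allele1"]), id=f"{row['locus_id']}_allele1", description="")
        )
        records.append(
            SeqRecord(Seq(row["allele2"]), id=f"{row['locus_id']}_allele2", description="")
        )
    if not records:
        warnings.warn("no retained polymorphic loci; writing empty reference")
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return len(records)
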