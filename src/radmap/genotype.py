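"""Genotype calling from exact-match allele read counts.

Each individual's tags are matched to the two-allele SNP reference by exact
string identity (tags equal to neither allele are ignored).  Calls use the
count thresholds of depth-based genotyping by sequencing: fewer than
``min_total`` (default 10) reads total is a missing call; otherwise with
f = n2 / (n1 + n2) the non-reference allele fraction, the call is AB iff
``het_low`` <= f <= ``het_high`` (default closed window [0.28, 0.80]),
BB above the window, AA below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .catalog import Catalog

MISSING = -1
CALL_STRINGS = {0: "AA", 1: "AB", 2: "BB", MISSING: "--"}
CALL_CODES = {v: k for k, v in CALL_STRINGS.items()}


@dataclass
class SNPReference:
    """Two allele sequences per mappable locus."""

    loci: pd.DataFrame  # locus_id, allele1, allele2

    @classmethod
    def from_catalog(cls, catalog: Catalog) -> "SNPReference":
        m = catalog.mappable()[["locus_id", "allele1", "allele2"]]
        return cls(loci=m.reset_index(drop=True))

    @classmethod
    def from_fasta(cls, path) -> "SNPReference":
        from Bio import SeqIO

        alleles: dict[str, dict[int, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            locus, _, which = rec.id.rpartition("_allele")
            alleles.setdefault(locus, {})[int(which)] = str(rec.seq)
        rows = [
            {"locus_id": locus, "allele1": d[1], "allele2": d[2]}
            for locus, d in sorted(alleles.items())
        ]
        return cls(loci=pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class AlleleCounts:
    """Read support per allele, loci x individuals."""

    loci: pd.Index
    individuals: list[str]
    n1: np.ndarray  # (n_loci, n_ind) int64
    n2: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.n1 + self.n2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, ind in enumerate(self.individuals):
            rows.append(
                pd.DataFrame(
                    {
                        "locus_id": self.loci,
                        "individual_id": ind,
                        "n1": self.n1[:, j],
                        "n2": self.n2[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def count_alleles(tag_streams, reference: SNPReference) -> AlleleCounts:
    """Exact-identity allele counting for each individual.

    ``tag_streams`` maps individual -> (m, 59) uint8 tag array, or a
    :class:`~radmap.readproc.TagStreams` (unique tags + counts).
    """
    from .readproc import TagStreams

    if isinstance(tag_streams, TagStreams):
        streams = {
            ind: (tag_streams.tags[ind], tag_streams.counts[ind])
            for ind in tag_streams.tags
        }
    else:
        streams = {
            ind: (arr, np.ones(arr.shape[0], dtype=np.int64))
            for ind, arr in tag_streams.items()
        }

    lookup: dict[bytes, tuple[int, int]] = {}
    for row, rec in enumerate(reference.loci.itertuples(index=False)):
        lookup[rec.allele1.encode("ascii")] = (row, 0)
        lookup[rec.allele2.encode("ascii")] = (row, 1)

    individuals = list(streams)
    n_loci = len(reference)
    n1 = np.zeros((n_loci, len(individuals)), dtype=np.int64)
    n2 = np.zeros((n_loci, len(individuals)), dtype=np.int64)
    for j, ind in enumerate(individuals):
        arr, weights = streams[ind]
        if arr.shape[0] == 0:
            continue
        uniq, inverse, _ = seqs.unique_rows(arr)
        summed = np.zeros(uniq.shape[0], dtype=np.int64)
        np.add.at(summed, inverse, np.asarray(weights, dtype=np.int64))
        for u in range(uniq.shape[0]):
            hit = lookup.get(uniq[u].tobytes())
            if hit is None:
                continue  # tags matching neither allele are ignored
            row, allele = hit
            if allele == 0:
                n1[row, j] += summed[u]
            else:
                n2[row, j] += summed[u]
    return AlleleCounts(
        loci=pd.Index(reference.loci["locus_id"]), individuals=individuals, n1=n1, n2=n2
    )


def call_genotype(n1: int, n2: int, min_total: int = 10,
                  het_lo: float = 0.28, het_hi: float = 0.80) -> str:
    """Call a single locus/individual from its two allele counts."""
    code = _call_codes(
        np.array([[n1]]), np.array([[n2]]), min_total, het_lo, het_hi
    )[0, 0]
    return CALL_STRINGS[int(code)]


def _call_codes(n1, n2, min_total, het_lo, het_hi):
    total = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, n2 / np.maximum(total, 1), 0.0)
    calls = np.where(f < het_lo, 0, np.where(f <= het_hi, 1, 2)).astype(np.int8)
    calls[total < min_total] = MISSING
    return calls


@dataclass
class GenotypeMatrix:
    """Loci x individuals genotype calls plus the parental calls.

    Codes count copies of allele2: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
    """

    loci: pd.Index
    offspring: list[str]
    calls: np.ndarray         # (n_loci, n_offspring) int8
    mother: np.ndarray        # (n_loci,) int8
    father: np.ndarray
    source: np.ndarray        # (n_loci,) object: 'rad' or 'assay'

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            loci=self.loci.copy(),
            offspring=list(self.offspring),
            calls=self.calls.copy(),
            mother=self.mother.copy(),
            father=self.father.copy(),
            source=self.source.copy(),
        )

    def subset(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            loci=self.loci[mask],
            offspring=list(self.offspring),
            calls=self.calls[mask],
            mother=self.mother[mask],
            father=self.father[mask],
            source=self.source[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        strings = np.array(["AA", "AB", "BB", "--"])
        df = pd.DataFrame(
            strings[self.calls], index=self.loci, columns=self.offspring
        )
        df.insert(0, "father", strings[self.father])
        df.insert(0, "mother", strings[self.mother])
        df.insert(0, "source", self.source)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="locus_id")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus_id", dtype=str)
        source = df.pop("source").to_numpy()
        mother = df.pop("mother").map(CALL_CODES).to_numpy(dtype=np.int8)
        father = df.pop("father").map(CALL_CODES).to_numpy(dtype=np.int8)
        calls = df.apply(lambda col: col.map(CALL_CODES)).to_numpy(dtype=np.int8)
        return cls(
            loci=df.index,
            offspring=list(df.columns),
            calls=calls,
            mother=mother,
            father=father,
            source=source,
        )

    def merge(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Append markers of another matrix over the same offspring."""
        if list(other.offspring) != list(self.offspring):
            raise ValueError("offspring sets differ; cannot merge matrices")
        return GenotypeMatrix(
            loci=self.loci.append(other.loci),
            offspring=list(self.offspring),
            calls=np.vstack([self.calls, other.calls]),
            mother=np.concatenate([self.mother, other.mother]),
            father=np.concatenate([self.father, other.father]),
            source=np.concatenate([self.source, other.source]),
        )


def call_family(counts: AlleleCounts, mother_id: str = "mother",
                father_id: str = "father", min_total: int = 10,
                het_lo: float = 0.28, het_hi: float = 0.80,
                source: str = "rad") -> GenotypeMatrix:
    """Call every individual (parents included) with the same thresholds."""
    codes = _call_codes(counts.n1, counts.n2, min_total, het_lo, het_hi)
    cols = {ind: j for j, ind in enumerate(counts.individuals)}
    if mother_id not in cols or father_id not in cols:
        raise ValueError("mother/father ids not present in counts")
    off = [ind for ind in counts.individuals if ind not in (mother_id, father_id)]
    off_idx = [cols[i] for i in off]
    return GenotypeMatrix(
        loci=counts.loci,
        offspring=off,
        calls=codes[:, off_idx],
        mother=codes[:, cols[mother_id]],
        father=codes[:, cols[father_id]],
        source=np.full(len(counts.loci), source, dtype=object),
    )


def genotyping_rate(gm: GenotypeMatrix) -> pd.Series:
    """Fraction of loci called (non-missing) per offspring."""
    rate = (gm.calls != MISSING).mean(axis=0)
    return pd.Series(rate, index=gm.offspring, name="genotyping_rate")


def genotyping_report(gm: GenotypeMatrix, counts: AlleleCounts | None = None) -> pd.DataFrame:
    """Per-individual genotyping rate with read totals (success-vs-depth table)."""
    report = genotyping_rate(gm).to_frame()
    if counts is not None:
        totals = pd.Series(
            counts.total.sum(axis=0), index=counts.individuals, name="aligned_reads"
        )
        report = report.join(totals.reindex(report.index))
    return report.reset_index(names="individual_id")
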