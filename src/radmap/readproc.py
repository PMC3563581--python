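"""Read processing: trimming, quality filtering and demultiplexing.

Raw barcoded reads become per-individual 59-nt RAD tag observations.
Platform-specific 3' trimming first (GAII reads lose their last 10 bases,
HiSeq reads are truncated to 70 bp), then the 80%-error-free quality rule,
then exact-match demultiplexing on the inline barcode followed by the SbfI
restriction-site remnant ``TGCAGG``.

The mean-correctness reading of the quality rule: each Phred score Q gives a
per-base probability of being correct p = 1 - 10^(-Q/10); a read is kept iff
the mean of p across the (trimmed) read is at least the threshold (default
0.80).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .config import ConfigError

REMNANT = "TGCAGG"
TAG_LENGTH = 59
TRIMMED_LENGTH = 70
PLATFORM_RAW_LENGTH = {"GAII": 80, "HiSeq": 100}


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    platform: str = "GAII"

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")
        if (self.qualities < 0).any():
            raise ValueError("Phred scores must be non-negative")


@dataclass
class ReadBatch:
    """Rectangular block of equal-length reads (ASCII uint8 + Phred uint8)."""

    seq: np.ndarray
    qual: np.ndarray
    platform: str = "GAII"

    def __len__(self) -> int:
        return self.seq.shape[0]

    @property
    def read_length(self) -> int:
        return self.seq.shape[1]


@dataclass
class ProcessingStats:
    """Read-count bookkeeping; categories partition the input exactly."""

    total: int = 0
    length_discarded: int = 0
    quality_discarded: int = 0
    unassigned: int = 0
    tag_n_discarded: int = 0
    assigned: int = 0
    per_individual: dict = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.total == (
            self.length_discarded
            + self.quality_discarded
            + self.unassigned
            + self.tag_n_discarded
            + self.assigned
        )

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "length_discarded": self.length_discarded,
            "quality_discarded": self.quality_discarded,
            "unassigned": self.unassigned,
            "tag_n_discarded": self.tag_n_discarded,
            "assigned": self.assigned,
            "per_individual": dict(self.per_individual),
        }


def trim_read(read: ReadRecord) -> ReadRecord | None:
    """Platform 3' trim; returns None for reads too short to trim to 70 nt."""
    if read.platform == "GAII":
        if len(read.sequence) < PLATFORM_RAW_LENGTH["GAII"]:
            return None
        return ReadRecord(
            read.read_id, read.sequence[:-10], read.qualities[:-10], read.platform
        )
    if read.platform == "HiSeq":
        if len(read.sequence) < TRIMMED_LENGTH:
            return None
        return ReadRecord(
            read.read_id,
            read.sequence[:TRIMMED_LENGTH],
            read.qualities[:TRIMMED_LENGTH],
            read.platform,
        )
    raise ValueError(f"unknown platform {read.platform!r}")


def mean_correct_probability(qual) -> float:
    q = np.asarray(qual, dtype=float)
    return float(np.mean(1.0 - 10.0 ** (-q / 10.0)))


def quality_filter(read: ReadRecord, threshold: float = 0.80) -> bool:
    """Keep iff mean per-base correctness >= threshold."""
    return mean_correct_probability(read.qualities) >= threshold


def trim_batch(batch: ReadBatch) -> tuple[ReadBatch, int]:
    """Vectorised trim; a whole batch shares one raw length by construction."""
    if batch.platform == "GAII":
        if batch.read_length < PLATFORM_RAW_LENGTH["GAII"]:
            return ReadBatch(batch.seq[:0], batch.qual[:0], batch.platform), len(batch)
        return (
            ReadBatch(batch.seq[:, :-10], batch.qual[:, :-10], batch.platform),
            0,
        )
    if batch.platform == "HiSeq":
        if batch.read_length < TRIMMED_LENGTH:
            return ReadBatch(batch.seq[:0], batch.qual[:0], batch.platform), len(batch)
        return (
            ReadBatch(
                batch.seq[:, :TRIMMED_LENGTH],
                batch.qual[:, :TRIMMED_LENGTH],
                batch.platform,
            ),
            0,
        )
    raise ValueError(f"unknown platform {batch.platform!r}")


_PHRED_CORRECT = 1.0 - 10.0 ** (-np.arange(256) / 10.0)


def quality_mask(batch: ReadBatch, threshold: float = 0.80) -> np.ndarray:
    total = np.zeros(len(batch))
    for j in range(batch.read_length):  # column sweep avoids a huge temporary
        total += _PHRED_CORRECT[batch.qual[:, j]]
    return total >= threshold * batch.read_length


def _check_manifest(manifest: pd.DataFrame) -> None:
    barcodes = manifest["barcode"]
    if barcodes.duplicated().any():
        raise ConfigError("duplicate barcodes in manifest")
    if barcodes.str.len().nunique() > 1:
        raise ConfigError("barcodes must share one length")


def demultiplex_batch(
    batch: ReadBatch,
    manifest: pd.DataFrame,
    barcode_length: int | None = None,
    remnant: str = REMNANT,
    tag_length: int = TAG_LENGTH,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Assign trimmed, quality-passed reads to individuals.

    A read is assigned iff its prefix equals an individual's barcode exactly
    and the following bases equal the restriction-site remnant; the next
    ``tag_length`` bases become the tag.  Tags containing non-ACGT symbols
    are discarded (the catalog relies on exact sequence identity).
    """
    _check_manifest(manifest)
    bl = barcode_length or len(manifest["barcode"].iloc[0])
    rem = seqs.encode(remnant)
    start = bl + len(rem)
    if batch.read_length < start + tag_length:
        raise ValueError(
            f"reads of length {batch.read_length} cannot hold barcode + remnant "
            f"+ {tag_length}-nt tag"
        )

    tags: dict[str, np.ndarray] = {
        ind: np.zeros((0, tag_length), dtype=np.uint8)
        for ind in manifest["individual_id"]
    }
    counts = {"unassigned": 0, "tag_n_discarded": 0, "assigned": 0}
    if len(batch) == 0:
        return tags, counts

    remnant_ok = (batch.seq[:, bl:start] == rem).all(axis=1)
    # pack barcode prefixes into integers for fast exact matching
    weights = (256 ** np.arange(bl - 1, -1, -1)).astype(np.int64)
    prefix_key = batch.seq[:, :bl].astype(np.int64) @ weights
    individuals = list(manifest["individual_id"])
    barcode_keys = seqs.encode_many(list(manifest["barcode"])).astype(np.int64) @ weights
    order_bc = np.argsort(barcode_keys)
    pos = np.searchsorted(barcode_keys[order_bc], prefix_key)
    pos = np.clip(pos, 0, len(order_bc) - 1)
    hit = barcode_keys[order_bc][pos] == prefix_key
    assign = np.where(hit, order_bc[pos], -1)
    assign[~remnant_ok] = -1

    tag_block = batch.seq[:, start : start + tag_length]
    acgt = seqs.is_acgt_rows(tag_block)
    counts["unassigned"] = int((assign < 0).sum())
    good = (assign >= 0) & acgt
    counts["tag_n_discarded"] = int(((assign >= 0) & ~acgt).sum())
    counts["assigned"] = int(good.sum())

    idx = np.flatnonzero(good)
    order = np.argsort(assign[idx], kind="stable")
    idx = idx[order]
    bounds = np.searchsorted(assign[idx], np.arange(len(individuals) + 1))
    for i, ind in enumerate(individuals):
        rows = idx[bounds[i] : bounds[i + 1]]
        if rows.size:
            tags[ind] = np.ascontiguousarray(tag_block[rows])
    return tags, counts


@dataclass
class TagStreams:
    """Per-individual unique tags with counts, plus processing statistics."""

    tags: dict[str, np.ndarray]      # individual -> (m, 59) uint8 unique tags
    counts: dict[str, np.ndarray]    # individual -> (m,) int64 occurrence counts
    stats: ProcessingStats

    def n_reads(self, individual: str) -> int:
        return int(self.counts[individual].sum())

    def write_tsv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ind in self.tags:
            pd.DataFrame(
                {"tag": seqs.decode_rows(self.tags[ind]), "count": self.counts[ind]}
            ).to_csv(outdir / f"{ind}_tags.tsv", sep="\t", index=False)


def process_batches(
    batches,
    manifest: pd.DataFrame,
    quality_threshold: float = 0.80,
    barcode_length: int | None = None,
    remnant: str = REMNANT,
) -> TagStreams:
    """Trim -> quality filter -> demultiplex a stream of read batches.

    ``batches`` is an iterable of :class:`ReadBatch` (or ``(name, batch)``
    pairs); output tags are collapsed to unique sequences with counts per
    individual.
    """
    stats = ProcessingStats(per_individual={ind: 0 for ind in manifest["individual_id"]})
    pools: dict[str, list[np.ndarray]] = {ind: [] for ind in manifest["individual_id"]}
    pool_counts: dict[str, list[np.ndarray]] = {
        ind: [] for ind in manifest["individual_id"]
    }

    for item in batches:
        batch = item[1] if isinstance(item, tuple) else item
        stats.total += len(batch)
        trimmed, dropped = trim_batch(batch)
        stats.length_discarded += dropped
        keep = quality_mask(trimmed, quality_threshold)
        stats.quality_discarded += int((~keep).sum())
        kept = ReadBatch(trimmed.seq[keep], trimmed.qual[keep], trimmed.platform)
        tags, counts = demultiplex_batch(
            kept, manifest, barcode_length=barcode_length, remnant=remnant
        )
        stats.unassigned += counts["unassigned"]
        stats.tag_n_discarded += counts["tag_n_discarded"]
        stats.assigned += counts["assigned"]
        for ind, arr in tags.items():
            if arr.shape[0]:
                uniq, _, cnt = seqs.unique_rows(arr)
                pools[ind].append(uniq)
                pool_counts[ind].append(cnt)
                stats.per_individual[ind] += int(arr.shape[0])

    tags_out: dict[str, np.ndarray] = {}
    counts_out: dict[str, np.ndarray] = {}
    for ind in pools:
        if pools[ind]:
            stacked = np.vstack(pools[ind])
            weights = np.concatenate(pool_counts[ind])
            uniq, inverse, _ = seqs.unique_rows(stacked)
            summed = np.zeros(uniq.shape[0], dtype=np.int64)
            np.add.at(summed, inverse, weights)
            tags_out[ind] = uniq
            counts_out[ind] = summed
        else:
            tags_out[ind] = np.zeros((0, TAG_LENGTH), dtype=np.uint8)
            counts_out[ind] = np.zeros(0, dtype=np.int64)
    return TagStreams(tags=tags_out, counts=counts_out, stats=stats)


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, optionally gzipped)

def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, platform: str = "GAII") -> ReadBatch:
    """Load a (possibly gzipped) FASTQ file of equal-length reads."""
    from Bio import SeqIO

    records = []
    with _open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            records.append(
                (str(rec.seq), rec.letter_annotations["phred_quality"])
            )
    if not records:
        return ReadBatch(
            np.zeros((0, 0), dtype=np.uint8), np.zeros((0, 0), dtype=np.uint8), platform
        )
    seq = seqs.encode_many([r[0] for r in records])
    qual = np.array([r[1] for r in records], dtype=np.uint8)
    return ReadBatch(seq=seq, qual=qual, platform=platform)


def write_fastq(batch: ReadBatch, path, id_prefix: str = "read") -> None:
    seq_strings = seqs.decode_rows(batch.seq)
    qual_strings = seqs.decode_rows((batch.qual + 33).astype(np.uint8))
    with _open(path, "wt") as fh:
        for i, (s, q) in enumerate(zip(seq_strings, qual_strings)):
            fh.write(f"@{id_prefix}_{i + 1}\n{s}\n+\n{q}\n")
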