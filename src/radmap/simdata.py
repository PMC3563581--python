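"""Synthetic outbred full-sib RAD-seq family with known truth.

The generator produces (a) a fully phased family truth — parental
haplotypes, per-offspring transmitted haplotypes, true genotypes, true
inter-marker recombination fractions per sex — and (b) barcoded FASTQ-style
reads with the read structure of an SbfI RAD library: inline barcode,
``TGCAGG`` restriction-site remnant, a 59-nt tag, and 3' filler bases.

Transmission is simulated directly as a Markov chain over ordered markers
(switch probability = the configured per-sex recombination fraction), so the
true rf between any adjacent pair is exactly known.  Collapsed-paralog (PSV)
loci are simulated as two duplicated copies with a fixed difference emitted
under a single tag, which makes every individual appear heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .config import ConfigError, SimConfig
from .readproc import ReadBatch

REMNANT = "TGCAGG"

CROSS_B3 = "B3"        # AB x AB
CROSS_D1 = "D1"        # AB x hom  (female informative)
CROSS_D2 = "D2"        # hom x AB  (male informative)
CROSS_FIXED = "fixed"  # AA x BB   (uninformative for mapping)
CROSS_PSV = "psv"      # collapsed paralog, presents as AB x AB


def generate_barcodes(n: int, length: int = 5) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= 2.

    Uses the parity-check code over the 4-letter alphabet: all words whose
    digit sum is 0 mod 4.  Any two distinct words of equal digit sum differ
    in at least two positions, giving single-error detection during
    demultiplexing.
    """
    capacity = 4 ** (length - 1)
    if n > capacity:
        raise ConfigError(
            f"cannot generate {n} barcodes of length {length} "
            f"(max {capacity} with distance >= 2)"
        )
    alphabet = "ACGT"
    codes = []
    for prefix in range(capacity):
        digits = [(prefix // 4**k) % 4 for k in range(length - 1)]
        digits.append((-sum(digits)) % 4)
        codes.append("".join(alphabet[d] for d in digits))
        if len(codes) == n:
            break
    return codes


@dataclass
class FamilyTruth:
    """Ground truth of one simulated family.

    Genotype codes count copies of ``allele_b`` (0 = AA, 1 = AB, 2 = BB,
    -1 = missing); ``allele_a`` is always the lexicographically smaller tag.
    """

    config: SimConfig
    loci: pd.DataFrame               # locus_id, chrom, order, snp_pos, cross_type, is_psv
    tags_a: np.ndarray               # (n_loci, tag_length) uint8
    tags_b: np.ndarray
    mother_haps: np.ndarray          # (n_loci, 2) int8 allele on each maternal homolog
    father_haps: np.ndarray
    mother_geno: np.ndarray          # (n_loci,) int8
    father_geno: np.ndarray
    genotypes: np.ndarray            # (n_loci, n_offspring) int8
    maternal_state: np.ndarray       # (n_loci, n_offspring) int8 homolog transmitted; -1 for PSV
    paternal_state: np.ndarray
    offspring: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def individuals(self) -> list[str]:
        return ["mother", "father"] + list(self.offspring)

    @property
    def clean_mask(self) -> np.ndarray:
        return ~self.loci["is_psv"].to_numpy()

    def allele_pairs(self) -> list[tuple[str, str]]:
        return list(zip(seqs.decode_rows(self.tags_a), seqs.decode_rows(self.tags_b)))

    def locus_table(self) -> pd.DataFrame:
        """Loci with allele sequences and parental genotypes, for export."""
        geno_str = np.array(["AA", "AB", "BB"])
        df = self.loci.copy()
        df["allele_a"] = seqs.decode_rows(self.tags_a)
        df["allele_b"] = seqs.decode_rows(self.tags_b)
        df["mother"] = geno_str[self.mother_geno]
        df["father"] = geno_str[self.father_geno]
        return df


def simulate_family(config: SimConfig, rng: np.random.Generator | None = None) -> FamilyTruth:
    """Simulate phased parents and Markovian meioses for one family."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])

    n_chrom = config.n_chromosomes
    per_clean = config.markers_per_chromosome
    n_off = config.n_offspring

    # Collapsed paralogs are *additional* apparent loci created by genome
    # duplication; they are interleaved among the clean markers so that they
    # make up psv_fraction of all loci without thinning the clean marker grid.
    f = config.psv_fraction
    extra = int(round(per_clean * f / (1.0 - f))) if f > 0 else 0
    per_chrom = per_clean + extra
    n_loci = n_chrom * per_chrom

    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)
    order = np.tile(np.arange(per_chrom), n_chrom)
    locus_id = [f"C{c:02d}M{m + 1:03d}" for c, m in zip(chrom, order)]
    is_psv = np.zeros(n_loci, dtype=bool)
    for c in range(n_chrom):
        if extra:
            pos = rng.choice(per_chrom, size=extra, replace=False)
            is_psv[c * per_chrom + pos] = True

    # allele sequences: one SNP per locus, allele_a lexicographically smaller
    tags_a = seqs.random_seqs(rng, n_loci, config.tag_length)
    snp_pos = rng.integers(0, config.tag_length, size=n_loci)
    tags_b = tags_a.copy()
    shift = rng.integers(1, 4, size=n_loci)
    base_idx = np.searchsorted(seqs.BASES, tags_a[np.arange(n_loci), snp_pos])
    tags_b[np.arange(n_loci), snp_pos] = seqs.BASES[(base_idx + shift) % 4]
    swap = np.array(
        [a.tobytes() > b.tobytes() for a, b in zip(tags_a, tags_b)]
    )
    tags_a[swap], tags_b[swap] = tags_b[swap].copy(), tags_a[swap].copy()

    # cross types
    kinds = np.array([CROSS_B3, CROSS_D1, CROSS_D2, CROSS_FIXED])
    cross = kinds[rng.choice(4, size=n_loci, p=list(config.informativeness_mix))]
    cross[is_psv] = CROSS_PSV

    # parental haplotypes: allele (0=a, 1=b) on each homolog
    mother_haps = np.zeros((n_loci, 2), dtype=np.int8)
    father_haps = np.zeros((n_loci, 2), dtype=np.int8)
    mother_het = np.isin(cross, [CROSS_B3, CROSS_D1])
    father_het = np.isin(cross, [CROSS_B3, CROSS_D2])
    for haps, het in ((mother_haps, mother_het), (father_haps, father_het)):
        which = rng.integers(0, 2, size=n_loci)
        haps[het, :] = np.stack([which[het], 1 - which[het]], axis=1)
    hom_allele = rng.integers(0, 2, size=n_loci)
    for haps, het, other_het in (
        (mother_haps, mother_het, father_het),
        (father_haps, father_het, mother_het),
    ):
        hom = ~het & (cross != CROSS_PSV)
        haps[hom, :] = hom_allele[hom, None]
    # fixed-difference loci: force the parents onto opposite alleles
    fixed = cross == CROSS_FIXED
    mother_haps[fixed, :] = hom_allele[fixed, None]
    father_haps[fixed, :] = 1 - hom_allele[fixed, None]

    mother_geno = mother_haps.sum(axis=1, dtype=np.int8)
    father_geno = father_haps.sum(axis=1, dtype=np.int8)
    mother_geno[is_psv] = 1
    father_geno[is_psv] = 1

    # Markov transmission over the clean markers of each chromosome, per
    # parent (the configured rf applies between adjacent clean markers; PSV
    # rows carry no transmission signal)
    maternal_state = np.zeros((n_loci, n_off), dtype=np.int8)
    paternal_state = np.zeros((n_loci, n_off), dtype=np.int8)
    for state, rf in (
        (maternal_state, config.inter_marker_rf_female),
        (paternal_state, config.inter_marker_rf_male),
    ):
        for c in range(n_chrom):
            rows = np.flatnonzero((chrom == c + 1) & ~is_psv)
            k = rows.size
            if k == 0:
                continue
            u = rng.random((k, n_off))
            switches = np.zeros((k, n_off), dtype=np.int8)
            switches[0] = u[0] < 0.5          # uniform starting homolog
            switches[1:] = u[1:] < rf         # recombination per interval
            state[rows] = np.cumsum(switches, axis=0) % 2

    rows = np.arange(n_loci)
    allele_m = mother_haps[rows[:, None], maternal_state]
    allele_p = father_haps[rows[:, None], paternal_state]
    genotypes = (allele_m + allele_p).astype(np.int8)
    genotypes[is_psv, :] = 1
    maternal_state[is_psv, :] = -1
    paternal_state[is_psv, :] = -1

    loci = pd.DataFrame(
        {
            "locus_id": locus_id,
            "chrom": chrom,
            "order": order,
            "snp_pos": snp_pos,
            "cross_type": cross,
            "is_psv": is_psv,
        }
    )
    offspring = [f"off{i + 1:03d}" for i in range(n_off)]
    return FamilyTruth(
        config=config,
        loci=loci,
        tags_a=tags_a,
        tags_b=tags_b,
        mother_haps=mother_haps,
        father_haps=father_haps,
        mother_geno=mother_geno,
        father_geno=father_geno,
        genotypes=genotypes,
        maternal_state=maternal_state,
        paternal_state=paternal_state,
        offspring=offspring,
    )


@dataclass
class ReadSimulation:
    """Realised read counts plus lazily materialised per-lane read batches."""

    config: SimConfig
    truth: FamilyTruth
    manifest: pd.DataFrame           # individual_id, barcode, lane
    count_a: np.ndarray              # (n_loci, n_individuals) reads carrying allele_a
    count_b: np.ndarray

    @property
    def individuals(self) -> list[str]:
        return list(self.manifest["individual_id"])

    @property
    def total_reads(self) -> int:
        return int(self.count_a.sum() + self.count_b.sum())

    def lane_names(self) -> list[str]:
        return sorted(self.manifest["lane"].unique())

    def iter_lanes(self):
        """Yield ``(lane_name, ReadBatch)``; deterministic and re-iterable."""
        cfg = self.config
        tag_rows = np.vstack([self.truth.tags_a, self.truth.tags_b])
        n_loci = self.truth.n_loci
        barcode_mat = seqs.encode_many(list(self.manifest["barcode"]))
        remnant = seqs.encode(REMNANT)
        fill_len = cfg.read_length - (cfg.barcode_length + len(REMNANT) + cfg.tag_length)
        ind_index = {ind: i for i, ind in enumerate(self.manifest["individual_id"])}

        for lane_no, lane in enumerate(self.lane_names()):
            rng = np.random.default_rng([cfg.seed, 2, lane_no])
            members = self.manifest.loc[self.manifest["lane"] == lane, "individual_id"]
            tag_idx_parts, ind_parts = [], []
            for ind in members:
                col = ind_index[ind]
                counts = np.concatenate([self.count_a[:, col], self.count_b[:, col]])
                idx = np.repeat(np.arange(2 * n_loci), counts)
                tag_idx_parts.append(idx)
                ind_parts.append(np.full(idx.size, col, dtype=np.int32))
            tag_idx = np.concatenate(tag_idx_parts)
            ind_idx = np.concatenate(ind_parts)
            n = tag_idx.size
            perm = rng.permutation(n)
            tag_idx, ind_idx = tag_idx[perm], ind_idx[perm]

            seq = np.empty((n, cfg.read_length), dtype=np.uint8)
            seq[:, : cfg.barcode_length] = barcode_mat[ind_idx]
            seq[:, cfg.barcode_length : cfg.barcode_length + len(REMNANT)] = remnant
            seq[:, cfg.barcode_length + len(REMNANT) : cfg.read_length - fill_len or None] = (
                tag_rows[tag_idx]
            )
            if fill_len:
                seq[:, -fill_len:] = seqs.random_seqs(rng, n, fill_len)

            qual = np.full((n, cfg.read_length), 35, dtype=np.uint8)
            fail = rng.random(n) < cfg.qual_fail_fraction
            qual[fail] = 2
            yield lane, ReadBatch(seq=seq, qual=qual, platform=cfg.platform)

    def write_fastq(self, outdir, gzip_output: bool = True) -> list[Path]:
        from .readproc import write_fastq

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for lane, batch in self.iter_lanes():
            suffix = ".fastq.gz" if gzip_output else ".fastq"
            path = outdir / f"{lane}{suffix}"
            write_fastq(batch, path, id_prefix=lane)
            paths.append(path)
        return paths


def simulate_reads(truth: FamilyTruth, config: SimConfig | None = None) -> ReadSimulation:
    """Draw per-locus read counts and package them as sequencing lanes.

    Coverage per locus per individual is negative binomial; heterozygote
    reads split Binomial(n, 1/2) between alleles; each read misreads the
    SNP-site allele with probability ``error_rate``.  PSV loci draw one
    coverage per duplicated copy so total depth doubles and both variants
    appear in roughly equal counts in every individual.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    n_loci = truth.n_loci
    individuals = truth.individuals
    n_ind = len(individuals)

    geno = np.column_stack(
        [truth.mother_geno, truth.father_geno, truth.genotypes]
    )  # (n_loci, n_ind)
    is_psv = truth.loci["is_psv"].to_numpy()

    mu = cfg.mean_coverage
    if cfg.coverage_dispersion is None:
        def draw(shape):
            return np.full(shape, int(round(mu)), dtype=np.int64)
    else:
        k = cfg.coverage_dispersion
        p = k / (k + mu)

        def draw(shape):
            return rng.negative_binomial(k, p, size=shape)

    count_a = np.zeros((n_loci, n_ind), dtype=np.int64)
    count_b = np.zeros((n_loci, n_ind), dtype=np.int64)

    clean = ~is_psv
    total = draw((int(clean.sum()), n_ind))
    g = geno[clean]
    n_b = np.where(g == 2, total, 0)
    het = g == 1
    n_b[het] = rng.binomial(total[het], 0.5)
    count_b[clean] = n_b
    count_a[clean] = total - n_b

    if is_psv.any():
        count_a[is_psv] = draw((int(is_psv.sum()), n_ind))  # copy carrying allele_a
        count_b[is_psv] = draw((int(is_psv.sum()), n_ind))

    if cfg.error_rate > 0:
        e = cfg.error_rate
        a_kept = rng.binomial(count_a, 1.0 - e)
        b_to_a = rng.binomial(count_b, e)
        total = count_a + count_b
        count_a = a_kept + b_to_a
        count_b = total - count_a

    barcodes = generate_barcodes(n_ind, cfg.barcode_length)
    lanes = [f"lane{(i // cfg.lane_size) + 1:02d}" for i in range(n_ind)]
    manifest = pd.DataFrame(
        {"individual_id": individuals, "barcode": barcodes, "lane": lanes}
    )
    return ReadSimulation(
        config=cfg, truth=truth, manifest=manifest, count_a=count_a, count_b=count_b
    )


def truth_genotype_matrix(truth: FamilyTruth):
    """Perfect-call genotype matrix straight from the simulated truth.

    Bypasses reads and calling entirely — useful for testing the QC and
    mapping stages under known genotypes.
    """
    from .genotype import GenotypeMatrix

    return GenotypeMatrix(
        loci=pd.Index(truth.loci["locus_id"]),
        offspring=list(truth.offspring),
        calls=truth.genotypes.copy(),
        mother=truth.mother_geno.copy(),
        father=truth.father_geno.copy(),
        source=np.full(truth.n_loci, "rad", dtype=object),
    )


def write_truth(truth: FamilyTruth, outdir) -> None:
    """Export ground-truth tables as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.locus_table().to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    geno_str = np.array(["AA", "AB", "BB"])
    pd.DataFrame(
        geno_str[truth.genotypes],
        index=truth.loci["locus_id"],
        columns=truth.offspring,
    ).to_csv(outdir / "truth_genotypes.tsv", sep="\t")
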