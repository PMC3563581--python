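"""End-to-end orchestration: simulate -> readproc -> catalog -> genotype -> qc -> map.

The in-memory pipeline (:func:`run_family_pipeline`) drives all analysis
stages on one simulated family and is what the CLI, the tests and the
recovery experiments use; the file-based stage runner in :mod:`radmap.cli`
wraps it with manifests and delimited-text outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import catalog as catalog_mod
from . import genotype as genotype_mod
from . import linkmap, markerqc, readproc, simdata
from .config import PipelineConfig


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, stage by stage."""

    config: PipelineConfig
    truth: simdata.FamilyTruth
    sim: simdata.ReadSimulation
    tag_streams: readproc.TagStreams
    catalog: catalog_mod.Catalog
    reference: genotype_mod.SNPReference
    counts: genotype_mod.AlleleCounts
    genotypes: genotype_mod.GenotypeMatrix
    qc: markerqc.QCResult
    pairs: pd.DataFrame
    maps: dict[str, linkmap.GeneticMap]

    def summary(self) -> dict:
        """Stage-by-stage counts (the monotone filter cascade)."""
        mappable = self.catalog.mappable()
        return {
            "total_reads": self.sim.total_reads,
            "assigned_reads": self.tag_streams.stats.assigned,
            "unique_parent_tags": int(
                len(
                    catalog_mod.count_unique_tags(
                        self.tag_streams.tags["mother"],
                        self.tag_streams.tags["father"],
                        self.tag_streams.counts["mother"],
                        self.tag_streams.counts["father"],
                    )
                )
            ),
            "catalog_loci": int(len(self.catalog.loci)),
            "putative_snps": int(len(mappable)),
            "qc_passed": int(self.qc.filtered.n_loci),
            "female_groups": len(self.maps["female"].groups),
            "male_groups": len(self.maps["male"].groups),
            "female_markers": self.maps["female"].n_markers,
            "male_markers": self.maps["male"].n_markers,
            "female_length_cM": round(self.maps["female"].total_length, 1),
            "male_length_cM": round(self.maps["male"].total_length, 1),
        }


def run_family_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a freshly simulated family."""
    config.validate()
    p = config.params
    sim_cfg = config.sim

    truth = simdata.simulate_family(sim_cfg)
    sim = simdata.simulate_reads(truth)
    streams = readproc.process_batches(
        sim.iter_lanes(),
        sim.manifest,
        quality_threshold=p.quality_threshold,
        barcode_length=sim_cfg.barcode_length,
        remnant=p.remnant,
    )
    cat = catalog_mod.build_catalog(
        streams.tags["mother"],
        streams.tags["father"],
        streams.counts["mother"],
        streams.counts["father"],
        min_count=p.min_tag_count,
        max_mismatches=p.max_mismatches,
    )
    reference = genotype_mod.SNPReference.from_catalog(cat)
    counts = genotype_mod.count_alleles(streams, reference)
    gm = genotype_mod.call_family(
        counts,
        min_total=p.min_total_reads,
        het_lo=p.het_low,
        het_hi=p.het_high,
    )
    qc = markerqc.run_qc(
        gm,
        max_error_fraction=p.max_inheritance_error,
        alpha=p.distortion_alpha,
        max_missing=p.max_missing,
    )
    engine = linkmap.TwoPointEngine(qc.filtered, qc.cross_types)
    pairs = engine.pairwise()
    maps = linkmap.build_sex_maps(
        qc.filtered,
        qc.cross_types,
        engine=engine,
        pairs=pairs,
        lod_bin=p.lod_bin,
        rf_bin=p.rf_bin,
        lod_group=p.lod_group,
        ripple_window=p.ripple_window,
        min_group_size=p.min_group_size,
    )
    return PipelineResult(
        config=config,
        truth=truth,
        sim=sim,
        tag_streams=streams,
        catalog=cat,
        reference=reference,
        counts=counts,
        genotypes=gm,
        qc=qc,
        pairs=pairs,
        maps=maps,
    )


def match_catalog_to_truth(result: PipelineResult) -> pd.DataFrame:
    """Join discovered loci back to simulated loci via allele sequences."""
    truth_tbl = result.truth.locus_table()
    by_allele = {row.allele_a: row.locus_id for row in truth_tbl.itertuples()}
    by_allele.update({row.allele_b: row.locus_id for row in truth_tbl.itertuples()})
    rows = []
    for _, rec in result.catalog.loci.iterrows():
        rows.append(
            {
                "locus_id": rec["locus_id"],
                "true_locus": by_allele.get(rec["allele1"]) or by_allele.get(rec["allele2"]),
                "status": rec["status"],
                "class": rec["class"],
            }
        )
    return pd.DataFrame(rows)


def group_recovery(result: PipelineResult) -> dict:
    """Compare recovered linkage groups with the simulated chromosomes."""
    out = {}
    match = match_catalog_to_truth(result).set_index("locus_id")["true_locus"]
    truth_chrom = result.truth.loci.set_index("locus_id")["chrom"]
    for sex, gmap in result.maps.items():
        purities = []
        for group in gmap.groups:
            members = [m for rep in group.markers for m in group.members[rep]]
            chroms = truth_chrom.reindex(match.reindex(members).dropna()).dropna()
            if len(chroms):
                purities.append((chroms == chroms.mode().iloc[0]).mean())
        out[sex] = {
            "n_groups": len(gmap.groups),
            "n_fragments": len(gmap.fragments),
            "mean_purity": float(np.mean(purities)) if purities else np.nan,
        }
    return out
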