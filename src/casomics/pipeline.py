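"""End-to-end pipeline orchestration over plain files.

Each stage reads and writes ordinary TSV/VCF/MTX files inside one run
directory, so stages are independently re-runnable and auditable. Every
output file is hashed into a provenance manifest together with the full
configuration and seed; reruns with an identical configuration reproduce
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (
    SimulationConfig,
    simulate_feature_snvs,
    simulate_hotspot_table,
    simulate_multiomics,
    simulate_variant_pair,
)
from . import chromatin, cnv, concordance, consequence, filters, io, scoring

log = logging.getLogger("casomics")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cas_run"
    # stage toggles
    run_filter: bool = True
    run_burden: bool = True
    run_score: bool = True
    run_cnv: bool = True
    run_atac: bool = True
    run_concord: bool = True
    # stage parameters
    cnv_cutoff: float = 0.85
    dar_fdr_max: float = 0.01
    dar_lfc_min: float = 0.3
    dar_k: int = 10
    link_score_min: float = 0.05
    link_distance_max: int = 500_000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages on freshly simulated inputs; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, lineterminator="\n")
        written.append(path)
        return path

    try:
        # ---- simulate ---------------------------------------------------
        log.info("stage simulate: seed=%d", sim.seed)
        records, vmanifest = simulate_variant_pair(sim)
        pair_vcf = outdir / "pair.vcf"
        contigs = {c: sim.chrom_length for c in sim.chromosomes}
        contigs["chrX"] = min(100_000, sim.chrom_length)
        io.write_vcf(records, pair_vcf, samples=[sim.ref_sample, sim.test_sample],
                     contigs=contigs)
        written.append(pair_vcf)
        save_tsv(vmanifest.variants, "truth_variants.tsv")

        multi = simulate_multiomics(sim)
        io.write_fasta(multi.genome, outdir / "genome.fa")
        io.write_gff3(multi.genes, outdir / "annotation.gff3")
        written += [outdir / "genome.fa", outdir / "annotation.gff3"]
        save_tsv(multi.segments, "segments.seg.tsv")
        io.write_matrix(multi.atac, outdir / "atac.mtx", outdir / "atac_features.tsv",
                        outdir / "atac_barcodes.tsv")
        io.write_matrix(multi.rna, outdir / "rna.mtx", outdir / "rna_features.tsv",
                        outdir / "rna_barcodes.tsv")
        written += [outdir / f"{m}{s}" for m in ("atac", "rna")
                    for s in (".mtx", "_features.tsv", "_barcodes.tsv")]
        save_tsv(pd.DataFrame({"barcode": multi.atac.barcodes,
                               "condition": multi.cell_conditions}), "cells.tsv")
        hotspots = simulate_hotspot_table(sim)
        save_tsv(hotspots, "hotspots.tsv")

        burden_records, burden_truth = simulate_feature_snvs(sim, multi.genome, multi.genes)
        burden_vcf = outdir / "burden.vcf"
        io.write_vcf(burden_records, burden_vcf,
                     samples=[sim.ref_sample, sim.test_sample], contigs=contigs)
        written.append(burden_vcf)
        save_tsv(burden_truth, "truth_burden_classes.tsv")

        # ---- filter -----------------------------------------------------
        passing = records
        if config.run_filter:
            verdicts, passing = filters.apply_filters(
                io.read_vcf(pair_vcf), sim.test_sample, sim.ref_sample
            )
            log.info("stage filter: %d/%d records pass", len(passing), len(verdicts))
            save_tsv(pd.DataFrame(filters.verdicts_to_rows(verdicts)), "verdicts.tsv")
            spectrum = filters.substitution_spectrum(
                [r for r in passing if r.is_biallelic_snv]
            )
            save_tsv(pd.DataFrame([spectrum]), "spectrum.tsv")

        # ---- burden -----------------------------------------------------
        calls = []
        if config.run_burden:
            genome_lengths = {c: len(s) for c, s in multi.genome.items() if c != "chrX"}
            calls = [
                consequence.call_consequence(rec, multi.genes, multi.genome)
                for rec in burden_records
            ]
            log.info("stage burden: %d consequence calls", len(calls))
            save_tsv(
                pd.DataFrame(
                    [{"variant_id": c.variant_id, "feature_class": c.feature_class,
                      "coding_consequence": c.coding_consequence, "gene": c.gene,
                      "aa_change": c.aa_change} for c in calls]
                ),
                "consequences.tsv",
            )
            result = consequence.burden_table(calls, multi.genes, genome_lengths)
            save_tsv(result.rates_frame(), "burden_rates.tsv")
            save_tsv(result.per_chromosome.reset_index(), "burden_per_chromosome.tsv")

        # ---- score ------------------------------------------------------
        if config.run_score:
            matrix = scoring.load_blosum100()
            table = scoring.HotspotTable.from_frame(hotspots)
            subs = tuple(
                scoring.Substitution(gene=c.gene, ref_aa=c.aa_ref,
                                     position=c.aa_pos, alt_aa=c.aa_alt)
                for c in calls
                if c.coding_consequence == "missense"
            )
            profiles = [scoring.MutationProfile(sample_id=sim.test_sample,
                                                substitutions=subs)]
            gene_sets = {"all_genes": {g.gene_id for g in multi.genes}}
            scores, ledger = scoring.score_samples(profiles, matrix, table, gene_sets)
            log.info("stage score: %d sample x gene-set rows", len(scores))
            save_tsv(scores, "impact_scores.tsv")
            save_tsv(ledger, "impact_ledger.tsv")

        # ---- cnv ----------------------------------------------------------
        gene_fc = {}
        if config.run_cnv:
            call_frames = []
            for cond in sim.conditions:
                segs = cnv.segments_from_frame(multi.segments, sample=cond)
                calls_ = cnv.call_cnv(segs, cutoff=config.cnv_cutoff)
                frame = cnv.calls_to_frame(calls_)
                frame.insert(0, "sample", cond)
                call_frames.append(frame)
                gene_fc[cond] = cnv.gene_copy_log2fc(segs, multi.genes)
            log.info("stage cnv: %d segments over %d conditions",
                     sum(map(len, call_frames)), len(sim.conditions))
            save_tsv(pd.concat(call_frames, ignore_index=True), "cnv_calls.tsv")
            save_tsv(pd.DataFrame(gene_fc), "cnv_gene_log2fc.tsv", index=True)

        # ---- atac ---------------------------------------------------------
        if config.run_atac:
            conditions = np.asarray(multi.cell_conditions)
            stats_frames = {}
            for cond in sim.effect_conditions:
                stats_frames[cond] = chromatin.dar_stats(multi.atac, conditions, cond)
            dars = chromatin.select_dars(
                pd.concat(stats_frames.values(), ignore_index=True)
                .sort_values("p_value", kind="mergesort")
                .drop_duplicates("peak"),
                fdr_max=config.dar_fdr_max, lfc_min=config.dar_lfc_min,
            )
            log.info("stage atac: %d DARs selected", len(dars))
            profiles = pd.DataFrame(
                {c: f.set_index("peak")["log2fc"] for c, f in stats_frames.items()}
            ).loc[dars["peak"]]
            k = min(config.dar_k, max(1, len(profiles)))
            if len(profiles) >= k and len(profiles) > 0:
                labels, centers = chromatin.group_dars(profiles, k=k, seed=config.seed)
                dars = dars.assign(group=labels.values)
            save_tsv(dars, "dars.tsv")
            if len(dars):
                score = chromatin.module_score(multi.atac, dars["peak"].tolist(),
                                               seed=config.seed)
                save_tsv(pd.DataFrame({"barcode": multi.atac.barcodes,
                                       "module_score": score}), "module_scores.tsv")
            links = chromatin.coaccessibility_links(
                multi.atac, distance_max=config.link_distance_max,
                score_min=config.link_score_min,
            )
            save_tsv(links, "coaccessibility_links.tsv")
            save_tsv(chromatin.link_target_genes(links, multi.atac, multi.genes),
                     "link_target_genes.tsv")
            focal = [p for p, g in multi.peak_to_gene.items()
                     if g in multi.manifest.concordant_genes][:3]
            if focal:
                activity, pcc = chromatin.tf_activity_and_pcc(
                    multi.atac, multi.motif_peaks, focal, seed=config.seed
                )
                save_tsv(activity, "tf_activity.tsv", index=True)
                save_tsv(pcc, "tf_pcc_ranking.tsv")

        # ---- concordance ---------------------------------------------------
        if config.run_concord and config.run_cnv:
            conds = list(sim.conditions)
            atac_pat = concordance.locus_log2fc(
                multi.atac, multi.cell_conditions, conds, sim.ref_sample,
                feature_to_gene=multi.peak_to_gene,
            )
            rna_pat = concordance.locus_log2fc(
                multi.rna, multi.cell_conditions, conds, sim.ref_sample,
            )
            cnv_pat = concordance.cnv_pattern(gene_fc, conds, sim.ref_sample)
            locus_genes = (multi.manifest.concordant_genes
                           + multi.manifest.copy_only_genes)
            atac_pat = atac_pat.loc[atac_pat.index.isin(locus_genes)]
            rna_pat = rna_pat.loc[rna_pat.index.isin(locus_genes)]
            cnv_pat = cnv_pat.loc[cnv_pat.index.isin(locus_genes)]
            sim_ar = concordance.similarity_table(atac_pat, rna_pat, "atac-rna")
            sim_cr = concordance.similarity_table(cnv_pat, rna_pat, "cnv-rna")
            comp = concordance.compare_similarity(sim_ar, sim_cr)
            log.info("stage concord: mean atac-rna minus cnv-rna similarity %.3f "
                     "(p=%.3g, n=%d)", comp.mean_difference, comp.p_value, comp.n_pairs)
            save_tsv(pd.concat([pat.add_prefix(f"{mod}_")
                                for mod, pat in (("cnv", cnv_pat), ("atac", atac_pat),
                                                 ("rna", rna_pat))], axis=1),
                     "locus_patterns.tsv", index=True)
            save_tsv(pd.DataFrame({"atac_rna": sim_ar, "cnv_rna": sim_cr}),
                     "similarity.tsv", index=True)
            (outdir / "similarity_test.json").write_text(
                json.dumps(dataclasses.asdict(comp), indent=2) + "\n"
            )
            written.append(outdir / "similarity_test.json")
    except Exception:
        (outdir / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise

    manifest = {
        "casomics_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in sorted(set(written)) if p.exists()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True) + "\n")
    return manifest
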