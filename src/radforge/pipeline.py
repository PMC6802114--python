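"""End-to-end orchestration: synthetic experiment -> trim -> cluster -> assemble
-> diversity / SSR / primers, with a JSON run manifest.

Read mapping and variant calling are intentionally pluggable: the pipeline
either consumes an externally produced VCF + depth table, or (in synthetic
mode) the truth VCF emitted by the generator, relabelled onto the assembled
tags by matching tag consensi against the simulated locus references.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import contigasm, diversity, primertools, readprep, ssrscan, synthdata, tagcluster
from .errors import ConfigurationError, PipelineStageError
from .io import write_fasta, write_fastq_pairs, write_tsv


@dataclass
class PipelineConfig:
    """Flat configuration covering every stage; defaults are the published
    parameter values where one exists."""

    seed: int = 0
    # synthetic experiment
    genome_length: int = 30_000
    n_individuals: int = 12
    n_pools: int = 2
    per_site_theta: float = 0.003
    ssr_plant_spec: list = field(default_factory=list)
    enzyme_site: str = "GAATTC"
    fragment_mean: int = 600
    fragment_sd: float = 100.0
    read_length: int = 100
    error_rate: float = 0.005
    coverage: float = 10.0
    locus_spacing: int = 1500
    # read-through trimming
    probe_size: int = 50
    max_distance: int = 5
    min_read_length: int = 30
    # clustering
    trim_to: int = 85
    min_stack_depth: int = 3
    max_stack_mismatches: int = 2
    max_locus_mismatches: int = 3
    repeat_depth_factor: float = 3.0
    # assembly / merging
    min_fwd_support: float = 0.10
    min_rev_support: float = 0.60
    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_penalty: float = -8.0
    min_score: float = 50.0
    min_identity: int = 10
    min_score_identity_ratio: float = 4.0
    # variant filtering / diversity
    min_qual: float = 300.0
    min_sample_depth: int = 5
    max_sample_depth: int = 200
    min_maf: float = 0.05
    min_individuals: int = 10
    drop_individuals: list = field(default_factory=list)
    min_presence: float = 0.8
    n_bootstrap: int = 10_000
    # SSR and primers
    min_border: int = 5
    min_alleles_primer: int = 3
    min_flank: int = 200
    flank_search: int = 200
    epcr_mismatches: int = 2
    epcr_gaps: int = 2
    run_ssr: bool = True
    run_primers: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> synthdata.SimulationConfig:
        return synthdata.SimulationConfig(
            seed=self.seed,
            genome_length=self.genome_length,
            n_individuals=self.n_individuals,
            n_pools=self.n_pools,
            per_site_theta=self.per_site_theta,
            ssr_plant_spec=[
                (m, tuple(r), c) for m, r, c in self.ssr_plant_spec
            ],
            enzyme_site=self.enzyme_site,
            fragment_mean=self.fragment_mean,
            fragment_sd=self.fragment_sd,
            read_length=self.read_length,
            error_rate=self.error_rate,
            coverage=self.coverage,
            locus_spacing=self.locus_spacing,
        )


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def match_tags_to_truth(
    tags: list[tagcluster.RadTag],
    truth: synthdata.TruthSet,
    max_mismatches: int = 5,
) -> dict[str, str]:
    """Map truth locus ids -> tag ids by comparing tag consensi (85 bp) against
    the reference prefix of each simulated locus; a locus maps only when
    exactly one tag matches within the mismatch budget."""
    prefix_len = len(tags[0].consensus) if tags else 85
    mapping: dict[str, str] = {}
    for locus in truth.loci:
        ref = truth.locus_reference(locus, prefix_len)
        best = []
        for tag in tags:
            if len(tag.consensus) != len(ref):
                continue
            d = sum(a != b for a, b in zip(tag.consensus, ref))
            if d <= max_mismatches:
                best.append(tag.tag_id)
        if len(best) == 1:
            mapping[locus.locus_id] = best[0]
    return mapping


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute all stages on a synthetic experiment and write outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "radforge_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        sim = config.sim_config()
        truth = synthdata.simulate_genome(sim)
        pairs = synthdata.simulate_reads(truth, sim)
        vcf_text, depth_table = synthdata.emit_truth_vcf(truth)
        write_fasta({"genome": truth.genome}, out / "genome.fasta")
        write_fastq_pairs(pairs, out / "reads_1.fastq.gz", out / "reads_2.fastq.gz")
        (out / "truth.vcf").write_text(vcf_text)
        write_tsv(depth_table, out / "depth.tsv")
        manifest["stages"][stage] = {
            "loci": len(truth.loci),
            "snps": len(truth.snps),
            "ssrs": len(truth.ssrs),
            "read_pairs": len(pairs),
        }
        _log(stage, f"{len(truth.loci)} loci, {len(pairs)} read pairs")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- trim ---------------------------------------------------------------
    stage = "trim"
    try:
        params = readprep.ScanParams(
            probe_size=config.probe_size,
            max_distance=config.max_distance,
            min_read_length=config.min_read_length,
        )
        kept: list[readprep.ReadPair] = []
        trimmed = discarded = 0
        for res in readprep.trim_pairs(pairs, params):
            if res.pair is None:
                discarded += 1
                continue
            if res.trimmed:
                trimmed += 1
            kept.append(res.pair)
        write_fastq_pairs(
            kept, out / "trimmed_1.fastq.gz", out / "trimmed_2.fastq.gz"
        )
        manifest["stages"][stage] = {
            "input_pairs": len(pairs),
            "trimmed": trimmed,
            "discarded": discarded,
            "kept": len(kept),
        }
        _log(stage, f"{trimmed} trimmed, {discarded} discarded")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- cluster ------------------------------------------------------------
    stage = "cluster"
    try:
        cparams = tagcluster.ClusterParams(
            trim_to=config.trim_to,
            min_stack_depth=config.min_stack_depth,
            max_stack_mismatches=config.max_stack_mismatches,
            max_locus_mismatches=config.max_locus_mismatches,
            repeat_depth_factor=config.repeat_depth_factor,
        )
        by_sample: dict[str, list[readprep.ReadPair]] = {}
        for p in kept:
            by_sample.setdefault(p.sample_id, []).append(p)
        stacks = {
            sample: tagcluster.build_stacks(
                tagcluster.prepare_forward_reads(plist, cparams.trim_to),
                cparams,
                sample=sample,
            )
            for sample, plist in sorted(by_sample.items())
        }
        tags = tagcluster.build_catalog(stacks, cparams)
        tags, n_repetitive = tagcluster.drop_repetitive(tags, cparams)
        allocation = tagcluster.allocate_pairs(tags, {p.read_id: p for p in kept})
        write_fasta(
            {t.tag_id: t.consensus for t in tags}, out / "catalog.fasta"
        )
        write_tsv(
            pd.DataFrame(
                [
                    {"tag_id": t.tag_id, "total_depth": t.total_depth}
                    | t.depth_by_sample
                    for t in tags
                ]
            ).fillna(0),
            out / "tags.tsv",
        )
        manifest["stages"][stage] = {
            "tags": len(tags),
            "repetitive_dropped": n_repetitive,
            "allocated_pairs": sum(len(v) for v in allocation.by_tag.values()),
        }
        _log(stage, f"{len(tags)} catalog tags")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- assemble -----------------------------------------------------------
    stage = "assemble"
    try:
        mparams = contigasm.MergeParams(
            match_score=config.match_score,
            mismatch_score=config.mismatch_score,
            gap_penalty=config.gap_penalty,
            min_score=config.min_score,
            min_identity=config.min_identity,
            min_score_identity_ratio=config.min_score_identity_ratio,
        )
        merged: list[contigasm.MergedContig] = []
        n_overlapped = 0
        for tag in tags:
            bin_pairs = allocation.by_tag.get(tag.tag_id, [])
            fwd = contigasm.assemble_forward(
                [p.forward_seq for p in bin_pairs], tag.tag_id
            )
            rev = contigasm.assemble_reverse(
                [p.reverse_seq for p in bin_pairs], tag.tag_id
            )
            m = contigasm.merge_tag(
                fwd,
                rev,
                mparams,
                min_fwd_support=config.min_fwd_support,
                min_rev_support=config.min_rev_support,
            )
            if m is not None:
                merged.append(m)
                n_overlapped += m.mode == "overlapped"
        if not merged:
            raise PipelineStageError(stage, "no tag produced a merged contig")
        pseudo, index = contigasm.build_pseudomolecule(merged)
        write_fasta(
            {
                f"{m.tag_id} {m.mode} fwd_support={m.fwd_support:.2f} "
                f"rev_support={m.rev_support:.2f}": m.sequence
                for m in merged
            },
            out / "contigs.fasta",
        )
        write_fasta({"pseudomolecule": pseudo}, out / "pseudomolecule.fasta")
        write_tsv(
            pd.DataFrame(
                index.entries, columns=["tag_id", "start0", "length"]
            ),
            out / "pseudomolecule_index.tsv",
        )
        manifest["stages"][stage] = {
            "merged_contigs": len(merged),
            "overlapped": n_overlapped,
            "n_joined": len(merged) - n_overlapped,
            "mean_length": float(np.mean([len(m.sequence) for m in merged])),
        }
        _log(stage, f"{len(merged)} contigs ({n_overlapped} overlapped)")
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- diversity ----------------------------------------------------------
    stage = "pi"
    try:
        locus_to_tag = match_tags_to_truth(tags, truth)
        samples, sites = diversity.read_vcf(str(out / "truth.vcf"))
        sites = [
            dataclasses.replace(s, contig=locus_to_tag[s.contig])
            for s in sites
            if s.contig in locus_to_tag
        ]
        depth = depth_table[depth_table["contig"].isin(locus_to_tag)].copy()
        depth["contig"] = depth["contig"].map(locus_to_tag)
        fparams = diversity.FilterParams(
            min_qual=config.min_qual,
            min_sample_depth=config.min_sample_depth,
            max_sample_depth=config.max_sample_depth,
            min_maf=config.min_maf,
            min_individuals=config.min_individuals,
        )
        ds1 = diversity.filter_variants(sites, fparams)
        samples2, ds2 = diversity.make_dataset2(
            ds1, samples, config.drop_individuals, config.min_presence
        )
        ds3 = diversity.make_dataset3(ds2)
        window_depth = depth[(depth["pos"] >= 11) & (depth["pos"] <= 80)]
        estimate = diversity.total_pi(
            ds2,
            window_depth,
            min_depth=config.min_sample_depth,
            min_presence=config.min_presence,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        (out / "pi.json").write_text(estimate.to_json() + "\n")
        write_tsv(diversity.per_site_pi_table(ds2), out / "persite_pi.tsv")
        manifest["stages"][stage] = {
            "vcf_sites": len(sites),
            "dataset1": len(ds1),
            "dataset2": len(ds2),
            "dataset3": len(ds3),
            "pi_total": estimate.pi_total,
            "ci": [estimate.ci_low, estimate.ci_high],
        }
        _log(stage, f"pi_total={estimate.pi_total:.6f}")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, str(e)) from e

    # --- SSR ----------------------------------------------------------------
    if config.run_ssr:
        stage = "ssr"
        try:
            contig_seqs = {m.tag_id: m.sequence for m in merged}
            all_loci: list[ssrscan.SsrLocus] = []
            n_genotyped = 0
            for tag_id in sorted(contig_seqs):
                loci = ssrscan.scan_perfect(
                    contig_seqs[tag_id], ssrscan.SsrParams(), contig=tag_id
                )
                reads_by_ind: dict[str, list[str]] = {}
                for p in allocation.by_tag.get(tag_id, []):
                    reads_by_ind.setdefault(p.sample_id, []).extend(
                        [p.forward_seq, p.reverse_seq]
                    )
                for locus in loci:
                    call = ssrscan.call_ssr_alleles(
                        locus,
                        contig_seqs[tag_id],
                        reads_by_ind,
                        min_border=config.min_border,
                    )
                    n_genotyped += call is not None
                all_loci.extend(loci)
            write_tsv(ssrscan.loci_table(all_loci), out / "ssr.tsv")
            comp = ssrscan.summarize_composition(all_loci)
            manifest["stages"][stage] = {
                "ssr_loci": len(all_loci),
                "genotyped": n_genotyped,
                "by_length": {
                    str(k): int(v)
                    for k, v in comp["by_length"]["count"].items()
                }
                if all_loci
                else {},
            }
            _log(stage, f"{len(all_loci)} SSR loci, {n_genotyped} genotyped")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, str(e)) from e
    else:
        all_loci = []
        contig_seqs = {m.tag_id: m.sequence for m in merged}

    # --- primers ------------------------------------------------------------
    if config.run_primers:
        stage = "primers"
        try:
            variants_by_contig: dict[str, list[int]] = {}
            for s in ds1:
                variants_by_contig.setdefault(s.contig, []).append(s.pos)
            rows = []
            panel_size = 0
            for locus in all_loci:
                if (
                    locus.left_flank < config.min_flank
                    or locus.right_flank < config.min_flank
                ):
                    continue
                if locus.alleles and locus.n_alleles < config.min_alleles_primer:
                    continue
                seq = contig_seqs[locus.contig]
                positions = [
                    p for p in variants_by_contig.get(locus.contig, [])
                    if p <= len(seq)
                ]
                masked = primertools.mask_variants(seq, positions)
                candidates = primertools.design_candidates(
                    locus, masked, flank_search=config.flank_search
                )
                if not candidates:
                    continue
                pair = candidates[0]
                hits = primertools.epcr(
                    pair,
                    contig_seqs,
                    max_mismatches=config.epcr_mismatches,
                    max_gaps=config.epcr_gaps,
                )
                unique = len(hits) == 1
                panel_size += unique
                rows.append(
                    {
                        "locus": pair.locus_id,
                        "left": pair.left_seq,
                        "right": pair.right_seq,
                        "product_size": pair.product_size,
                        "tm_left": round(pair.tm_left, 2),
                        "tm_right": round(pair.tm_right, 2),
                        "gc_left": round(pair.gc_left, 3),
                        "gc_right": round(pair.gc_right, 3),
                        "products": len(hits),
                        "high_quality": unique,
                    }
                )
            write_tsv(pd.DataFrame(rows), out / "primers.tsv")
            manifest["stages"][stage] = {
                "designed": len(rows),
                "high_quality": panel_size,
            }
            _log(stage, f"{len(rows)} primer pairs, {panel_size} high quality")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, str(e)) from e

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
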