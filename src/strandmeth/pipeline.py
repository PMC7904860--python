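"""Pipeline configuration and end-to-end orchestration.

A run is described by a YAML config (unknown keys are rejected).  The
stages execute in order simulate -> demux -> call -> bias ->
cluster/sisters; every output file is hashed into a provenance manifest
and the resolved configuration is written beside the outputs, so a
rerun with the same config and seeds reproduces the hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as smio
from .demux import BarcodeTable, demultiplex_fastq
from .heterogeneity import build_matrix, cluster_cells, find_sisters
from .simulate import SimGenome, SimParams, make_genome, simulate_cell_reads
from .sitecall import assign_allele, call_sites, dedup
from .strandbias import compute_bias, plus_minus_correlation

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _check_keys(section: Dict[str, Any], allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class SimulateConfig:
    n_chrom: int = 2
    chrom_len: int = 5000
    gc: float = 0.5
    snp_rate: float = 0.005
    n_cells: int = 4
    read_len: int = 75
    m_parent: float = 0.8
    e_maint: float = 0.95
    d_cpa: float = 0.02
    h_frac: float = 0.05
    capture_eff: float = 0.5
    dup_rate: float = 1.0


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    reference: Optional[str] = None     # FASTA; filled in by simulate stage
    barcodes: Optional[str] = None      # TSV barcode table
    snps: Optional[str] = None          # VCF
    reads: Optional[str] = None         # FASTQ to demultiplex
    alignments: Optional[str] = None    # tagged SAM for site calling
    simulate: Optional[SimulateConfig] = None
    demux_max_mismatch: int = 0
    call_offset: int = 16
    bias_grouping: str = "chromosome"
    bias_context: str = "CpG"
    bias_min_sites: int = 50
    bias_alpha: float = 0.05
    cluster_k_range: List[int] = field(default_factory=lambda: [2, 3, 4, 5])
    cluster_n_restarts: int = 10
    cluster_min_regions: int = 3
    sisters_r_threshold: float = -0.8
    sisters_min_shared: int = 3

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        allowed = {f.name for f in dataclasses.fields(cls)}
        _check_keys(raw, allowed, "pipeline config")
        sim = raw.pop("simulate", None)
        if sim is not None:
            _check_keys(sim, {f.name for f in dataclasses.fields(SimulateConfig)},
                        "simulate")
            sim = SimulateConfig(**sim)
        if "outdir" not in raw:
            raise ConfigError("config requires 'outdir'")
        return cls(simulate=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is None:
            d.pop("simulate")
        return d

    def validate_inputs(self) -> None:
        if self.simulate is None:
            for name in ("reference", "alignments"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"without a simulate stage, '{name}' is required")
                if not os.path.exists(path):
                    raise ConfigError(f"{name} path does not exist: {path}")
        for name in ("reference", "barcodes", "snps", "reads", "alignments"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")


def simulate_and_call(
    genome: SimGenome,
    params: SimParams,
    workdir: str,
    read_len: int = 75,
    parental_maps: Optional[Dict[int, Dict[tuple, str]]] = None,
    with_alleles: bool = False,
):
    """Simulate a cohort and run the call stage on its truth alignments.

    Emits reads for every cell into one SAM under ``workdir``, then runs
    site calling, deduplication and (optionally) allele assignment.
    Returns ``(calls, truth_fragments, stats)`` where ``calls`` is the
    deduplicated call table with cell labels ``cell0..cellN-1``.

    ``parental_maps`` optionally fixes the parental-strand map per cell
    id (e.g. to plant sister pairs).
    """
    smio.ensure_dir(workdir)
    all_reads = []
    truth_frags: Dict[int, list] = {}
    for cell_id in range(params.n_cells):
        parental = None if parental_maps is None else parental_maps.get(cell_id)
        _truth, frags, reads = simulate_cell_reads(
            genome, params, cell_id, read_len=read_len, parental=parental)
        all_reads.extend(reads)
        truth_frags[cell_id] = frags
    sam_path = os.path.join(workdir, "cohort.sam")
    smio.write_truth_sam(all_reads, genome, sam_path)
    from .sitecall import assign_allele, call_sites, dedup  # local to avoid cycle
    calls, stats = call_sites(sam_path, genome.chromosomes)
    calls = dedup(calls)
    if with_alleles:
        calls = assign_allele(calls, sam_path, genome.snps, genome.chromosomes)
    label = {params.barcodes[i]: f"cell{i}" for i in range(params.n_cells)}
    calls["cell"] = calls["cell"].map(label)
    return calls, truth_frags, stats


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Execute the configured stages; returns the provenance manifest."""
    config.validate_inputs()
    outdir = smio.ensure_dir(config.outdir)
    manifest: Dict[str, Any] = {"stages": {}, "outputs": {}}

    def record(stage: str, *paths: str) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            rel = os.path.relpath(p, outdir)
            manifest["stages"][stage].append(rel)
            manifest["outputs"][rel] = _sha256(p)

    # ---- simulate -------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        genome = make_genome(sim.n_chrom, sim.chrom_len, sim.gc,
                             sim.snp_rate, config.seed)
        params = SimParams(m_parent=sim.m_parent, e_maint=sim.e_maint,
                           d_cpa=sim.d_cpa, h_frac=sim.h_frac,
                           capture_eff=sim.capture_eff, dup_rate=sim.dup_rate,
                           n_cells=sim.n_cells, seed=config.seed)
        ref_path = os.path.join(outdir, "reference.fa")
        smio.write_fasta(genome.chromosomes, ref_path)
        vcf_path = os.path.join(outdir, "snps.vcf")
        smio.write_vcf(genome.snps,
                       {c: len(s) for c, s in genome.chromosomes.items()},
                       vcf_path)
        bc_path = os.path.join(outdir, "barcodes.tsv")
        with open(bc_path, "w") as fh:
            fh.write("# barcode\tcell\n")
            for i in range(sim.n_cells):
                fh.write(f"{params.barcodes[i]}\tcell{i}\n")
        all_reads = []
        truth_rows = []
        for cell_id in range(sim.n_cells):
            truth, frags, reads = simulate_cell_reads(
                genome, params, cell_id, read_len=sim.read_len)
            all_reads.extend(reads)
            for f in frags:
                truth_rows.append((f"cell{cell_id}", f.chrom, f.mC_pos0,
                                   f.mC_strand, f.allele, f.umi, f.cut_pos0))
        fastq_path = os.path.join(outdir, "reads.fastq")
        smio.write_fastq(((r.read_id, r.sequence, r.quality) for r in all_reads),
                         fastq_path)
        sam_path = os.path.join(outdir, "truth.sam")
        smio.write_truth_sam(all_reads, genome, sam_path)
        truth_path = os.path.join(outdir, "truth_fragments.tsv")
        smio.write_tsv(pd.DataFrame(
            truth_rows, columns=["cell", "chrom", "pos0", "strand",
                                 "allele", "umi", "cut_pos0"]), truth_path)
        record("simulate", ref_path, vcf_path, bc_path, fastq_path,
               sam_path, truth_path)
        config.reference = ref_path
        config.barcodes = bc_path
        config.snps = vcf_path
        config.reads = fastq_path
        config.alignments = sam_path

    reference = smio.read_fasta(config.reference)

    # ---- demux ----------------------------------------------------------
    if config.reads is not None and config.barcodes is not None:
        table = BarcodeTable.from_tsv(config.barcodes)
        tagged_path = os.path.join(outdir, "demux.fastq")
        result = demultiplex_fastq(config.reads, table,
                                   max_mismatch=config.demux_max_mismatch,
                                   fastq_out=tagged_path)
        report_path = os.path.join(outdir, "demux_report.tsv")
        smio.write_tsv(result.report(), report_path)
        record("demux", tagged_path, report_path)

    # ---- call -----------------------------------------------------------
    calls, stats = call_sites(config.alignments, reference,
                              offset=config.call_offset)
    calls = dedup(calls)
    if config.snps is not None:
        snps = smio.read_snps(config.snps)
        calls = assign_allele(calls, config.alignments, snps, reference,
                              offset=config.call_offset)
    # map barcodes to cell labels when a table is available
    if config.barcodes is not None:
        table = BarcodeTable.from_tsv(config.barcodes)
        calls["cell"] = calls["cell"].map(lambda b: table.entries.get(b, b))
    calls_path = os.path.join(outdir, "calls.tsv")
    smio.write_tsv(calls, calls_path)
    stats_path = os.path.join(outdir, "call_stats.tsv")
    smio.write_tsv(pd.DataFrame([dataclasses.asdict(stats)]), stats_path)
    record("call", calls_path, stats_path)

    # ---- bias -----------------------------------------------------------
    chrom_sizes = {c: len(s) for c, s in reference.items()}
    records = compute_bias(calls, grouping=config.bias_grouping,
                           context=config.bias_context,
                           min_sites=config.bias_min_sites,
                           alpha=config.bias_alpha, chrom_sizes=chrom_sizes)
    bias_path = os.path.join(outdir, "strand_bias.tsv")
    smio.write_tsv(records, bias_path)
    corr = plus_minus_correlation(calls, grouping=config.bias_grouping,
                                  context=config.bias_context,
                                  chrom_sizes=chrom_sizes)
    corr_path = os.path.join(outdir, "plus_minus_correlation.tsv")
    smio.write_tsv(corr, corr_path)
    record("bias", bias_path, corr_path)

    # ---- cluster / sisters ---------------------------------------------
    try:
        matrix = build_matrix(records, min_regions=config.cluster_min_regions)
    except ValueError as exc:
        logger.warning("skipping cluster/sister stages: %s", exc)
        matrix = None
    if matrix is not None:
        matrix_path = os.path.join(outdir, "bias_matrix.tsv")
        with open(matrix_path, "w") as fh:
            fh.write(smio.TSV_COMMENT + "\n")
            matrix.to_frame().to_csv(fh, sep="\t", index_label="cell")
        paths = [matrix_path]
        k_max = max(config.cluster_k_range)
        if len(matrix.cells) >= 2 * k_max:
            result = cluster_cells(matrix, k_range=config.cluster_k_range,
                                   n_restarts=config.cluster_n_restarts,
                                   seed=config.seed)
            clusters_path = os.path.join(outdir, "clusters.tsv")
            smio.write_tsv(result.to_frame(), clusters_path)
            paths.append(clusters_path)
        else:
            logger.warning("too few cells for k-means up to k=%d; skipping", k_max)
        pairs = find_sisters(matrix, r_threshold=config.sisters_r_threshold,
                             min_shared=config.sisters_min_shared)
        sisters_path = os.path.join(outdir, "sisters.tsv")
        smio.write_tsv(pd.DataFrame(
            [dataclasses.asdict(p) for p in pairs],
            columns=["cell_a", "cell_b", "r"]), sisters_path)
        paths.append(sisters_path)
        record("cluster", *paths)

    # ---- provenance -----------------------------------------------------
    resolved_path = os.path.join(outdir, "config_resolved.yaml")
    with open(resolved_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
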