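"""5mC site calling from mapped, tagged reads.

MspJI cuts 16 bp downstream of the methylated cytosine on the 5mC
strand, and sequencing starts from the ligated cut end, so a read maps
antisense to the strand that carried the 5mC:

* a minus-strand read with 5' genomic end ``p`` implies a plus-strand
  5mC at ``p - offset``;
* a plus-strand read with 5' genomic end ``p`` implies a minus-strand
  5mC at ``p + offset``.

A candidate becomes a call only when the reference actually has a
cytosine at that position on that strand; everything else is counted as
off-geometry.  The dinucleotide context (CpG/CpA/CpC/CpT) is read from
the reference base following the cytosine on the 5mC strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .io import TAG_CELL, TAG_UMI
from .util import CUT_OFFSET, complement

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["cell", "chrom", "pos0", "strand", "context", "allele", "umi", "support"]

_CONTEXT = {"G": "CpG", "A": "CpA", "C": "CpC", "T": "CpT"}

ALLELE_UNKNOWN = "unknown"
ALLELE_LABELS = {1: "allele1", 2: "allele2"}


@dataclass
class CallStats:
    """Bookkeeping for candidates that did not become calls."""

    n_reads: int = 0
    n_called: int = 0
    n_out_of_range: int = 0
    n_off_geometry: int = 0  # reference base at the candidate is not C
    n_no_context: int = 0    # context base would fall outside the chromosome

    @property
    def off_geometry_rate(self) -> float:
        return self.n_off_geometry / self.n_reads if self.n_reads else 0.0


def _candidate(reverse: bool, five_prime: int, offset: int) -> Tuple[int, str]:
    if reverse:
        return five_prime - offset, "+"
    return five_prime + offset, "-"


def call_sites(
    sam_in: str,
    reference: Dict[str, str],
    offset: int = CUT_OFFSET,
) -> Tuple[pd.DataFrame, CallStats]:
    """Convert tagged alignments into per-read 5mC candidate calls.

    Returns a pre-deduplication call table (one row per read, support=1)
    and counter statistics.  Reads must carry cell (CB) and UMI (RX)
    tags.
    """
    rows: List[tuple] = []
    stats = CallStats()
    with pysam.AlignmentFile(sam_in, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            stats.n_reads += 1
            chrom = aln.reference_name
            seq = reference.get(chrom)
            if seq is None:
                stats.n_out_of_range += 1
                continue
            if aln.is_reverse:
                five_prime = aln.reference_end - 1
            else:
                five_prime = aln.reference_start
            pos0, strand = _candidate(aln.is_reverse, five_prime, offset)
            if not 0 <= pos0 < len(seq):
                stats.n_out_of_range += 1
                continue
            base = seq[pos0]
            ref_c = base == "C" if strand == "+" else base == "G"
            if not ref_c:
                stats.n_off_geometry += 1
                continue
            if strand == "+":
                if pos0 + 1 >= len(seq):
                    stats.n_no_context += 1
                    continue
                ctx_base = seq[pos0 + 1]
            else:
                if pos0 - 1 < 0:
                    stats.n_no_context += 1
                    continue
                ctx_base = complement(seq[pos0 - 1])
            context = _CONTEXT.get(ctx_base)
            if context is None:
                stats.n_no_context += 1
                continue
            cell = aln.get_tag(TAG_CELL)
            umi = aln.get_tag(TAG_UMI)
            rows.append((cell, chrom, pos0, strand, context, ALLELE_UNKNOWN, umi, 1))
            stats.n_called += 1
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls, stats


def dedup(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR/IVT duplicates.

    One call per distinct (cell, chrom, pos0, strand, umi); ``support``
    sums the collapsed read counts.  Output order is deterministic:
    sorted by chrom, pos0, strand, cell, umi.  Idempotent.
    """
    if calls.empty:
        return calls.copy()
    key = ["cell", "chrom", "pos0", "strand", "umi"]
    out = (calls.groupby(key, as_index=False, sort=False)
           .agg(context=("context", "first"),
                allele=("allele", "first"),
                support=("support", "sum")))
    out = out[CALL_COLUMNS]
    out = out.sort_values(["chrom", "pos0", "strand", "cell", "umi"],
                          kind="mergesort").reset_index(drop=True)
    return out


def _read_allele_evidence(
    aln: pysam.AlignedSegment,
    snps_by_chrom: Dict[str, Dict[int, Tuple[str, str]]],
) -> Optional[int]:
    """Allele supported by the SNPs a read covers.

    Returns 1, 2, None (no informative SNP) or 0 (conflicting / bases
    matching neither haplotype).
    """
    chrom_snps = snps_by_chrom.get(aln.reference_name)
    if not chrom_snps:
        return None
    start, end = aln.reference_start, aln.reference_end
    seq = aln.query_alignment_sequence
    seen: set = set()
    for pos0 in range(start, end):
        hit = chrom_snps.get(pos0)
        if hit is None:
            continue
        ref, alt = hit
        base = seq[pos0 - start]
        if base == ref:
            seen.add(1)
        elif base == alt:
            seen.add(2)
        else:
            seen.add(0)
    if not seen:
        return None
    if seen == {1}:
        return 1
    if seen == {2}:
        return 2
    return 0


def assign_allele(
    calls: pd.DataFrame,
    sam_in: str,
    snps: Sequence[Tuple[str, int, str, str]],
    reference: Dict[str, str],
    offset: int = CUT_OFFSET,
) -> pd.DataFrame:
    """Label calls with their parental haplotype via strain SNPs.

    Every supporting read of a call is inspected at the SNP positions it
    covers; calls whose reads consistently match haplotype 1 (reference
    base) or haplotype 2 (alternate base) are labelled, anything
    conflicting or uninformative stays ``unknown``.  SNPs whose stated
    reference base disagrees with the reference FASTA are dropped with a
    warning.
    """
    snps_by_chrom: Dict[str, Dict[int, Tuple[str, str]]] = {}
    n_bad = 0
    for chrom, pos0, ref, alt in snps:
        seq = reference.get(chrom)
        if seq is None or not (0 <= pos0 < len(seq)) or seq[pos0] != ref:
            n_bad += 1
            continue
        snps_by_chrom.setdefault(chrom, {})[pos0] = (ref, alt)
    if n_bad:
        logger.warning("dropped %d SNPs whose ref base disagrees with the reference", n_bad)

    # accumulate evidence per call key across supporting reads
    evidence: Dict[tuple, set] = {}
    with pysam.AlignmentFile(sam_in, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                five_prime = aln.reference_end - 1
            else:
                five_prime = aln.reference_start
            pos0, strand = _candidate(aln.is_reverse, five_prime, offset)
            key = (aln.get_tag(TAG_CELL), aln.reference_name, pos0, strand,
                   aln.get_tag(TAG_UMI))
            ev = _read_allele_evidence(aln, snps_by_chrom)
            if ev is not None:
                evidence.setdefault(key, set()).add(ev)

    def label(row) -> str:
        ev = evidence.get((row.cell, row.chrom, row.pos0, row.strand, row.umi))
        if ev == {1}:
            return ALLELE_LABELS[1]
        if ev == {2}:
            return ALLELE_LABELS[2]
        return ALLELE_UNKNOWN

    out = calls.copy()
    if not out.empty:
        out["allele"] = [label(row) for row in out.itertuples()]
    return out
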