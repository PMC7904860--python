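"""Readers and writers for the formats the pipeline exchanges.

SAM records are written/read through pysam; VCFs are read through
pysam.VariantFile.  Tabular outputs are TSV with a leading ``#`` comment
line naming the coordinate convention (positions in files are 1-based;
everything in memory is 0-based half-open).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
import pysam

from .simulate import SimGenome, SimRead

#: SAM tag carrying the cell barcode / label
TAG_CELL = "CB"
#: SAM tag carrying the UMI
TAG_UMI = "RX"
#: SAM tag carrying the truth allele (simulator output only)
TAG_ALLELE = "XL"
#: SAM tag carrying the truth 5mC position (simulator output only)
TAG_TRUE_POS = "XT"

TSV_COMMENT = "# strandmeth table; 'pos' columns are 1-based, ranges are 1-based inclusive"


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence.upper()
    return out


def write_fastq(records: Iterable[Tuple[str, str, str]], path: str) -> int:
    """Write (read_id, sequence, quality) triples; returns the count."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str):
    """Yield (read_id, comment, sequence, quality) from a FASTQ file."""
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield entry.name, entry.comment, entry.sequence, entry.quality


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam_header(chrom_lengths: Dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        "PG": [{"ID": "strandmeth", "PN": "strandmeth"}],
    })


def write_truth_sam(reads: Sequence[SimRead], genome: SimGenome, path: str) -> int:
    """Write simulator reads as truth alignments (plain-text SAM).

    The stored SEQ is the genomic portion in reference orientation; the
    UMI/barcode prefix lives in tags, as it would after demultiplexing
    and trimming.
    """
    header = sam_header({c: len(s) for c, s in genome.chromosomes.items()})
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.genomic_fwd
            a.flag = 16 if r.reverse else 0
            a.reference_id = fh.get_tid(r.chrom)
            a.reference_start = r.ref_start0
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.genomic_fwd)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.genomic_fwd))
            a.set_tag(TAG_CELL, r.cell_barcode, "Z")
            a.set_tag(TAG_UMI, r.umi, "Z")
            a.set_tag(TAG_ALLELE, r.allele, "i")
            a.set_tag(TAG_TRUE_POS, r.mC_pos0, "i")
            fh.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(snps: Sequence[Tuple[str, int, str, str]],
              chrom_lengths: Dict[str, int], path: str) -> None:
    """Write SNPs as a minimal plain-text VCF (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in snps:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_snps(path: str) -> List[Tuple[str, int, str, str]]:
    """Read biallelic SNPs from a VCF; returns (chrom, pos0, ref, alt)."""
    out: List[Tuple[str, int, str, str]] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue  # SNPs only
            out.append((rec.chrom, rec.pos - 1, ref, alt))
    return out


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a table with the package's comment header.

    Any ``pos0`` column is converted to a 1-based ``pos`` column on the
    way out.
    """
    out = df.copy()
    if "pos0" in out.columns:
        out.insert(list(out.columns).index("pos0"), "pos", out["pos0"] + 1)
        out = out.drop(columns=["pos0"])
    with open(path, "w") as fh:
        fh.write(TSV_COMMENT + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    """Read a table written by write_tsv; restores 0-based ``pos0``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "pos" in df.columns and "pos0" not in df.columns:
        df.insert(list(df.columns).index("pos"), "pos0", df["pos"] - 1)
        df = df.drop(columns=["pos"])
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
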