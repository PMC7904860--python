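"""Cell-barcode demultiplexing and UMI extraction.

Reads carry the layout [UMI 3 nt][cell barcode 8 nt][genomic portion].
A read is assigned to a cell iff exactly one table barcode matches the
barcode field within ``max_mismatch`` Hamming distance; ties and
no-matches are counted as unassigned with a reason.  UMIs are kept
verbatim — with only 64 possible 3-mers, error correction would merge
distinct molecules.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from . import io as smio
from .util import BARCODE_LEN, UMI_LEN, hamming

logger = logging.getLogger(__name__)

_PREFIX_LEN = UMI_LEN + BARCODE_LEN


@dataclass
class BarcodeTable:
    """Mapping from 8-nt barcode sequence to cell label."""

    entries: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode table is empty")
        lengths = {len(b) for b in self.entries}
        if lengths != {BARCODE_LEN}:
            raise ValueError(
                f"all barcodes must be {BARCODE_LEN} nt, got lengths {sorted(lengths)}")
        bcs = list(self.entries)
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                if hamming(bcs[i], bcs[j]) < 2:
                    warnings.warn(
                        f"barcodes {bcs[i]} and {bcs[j]} have Hamming distance "
                        "< 2; one-mismatch demultiplexing will be ambiguous",
                        stacklevel=2)

    @classmethod
    def from_tsv(cls, path: str) -> "BarcodeTable":
        entries: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    entries[parts[0]] = parts[0]
                else:
                    entries[parts[0]] = parts[1]
        return cls(entries)

    @classmethod
    def from_barcodes(cls, barcodes: Iterable[str]) -> "BarcodeTable":
        return cls({bc: bc for bc in barcodes})


@dataclass
class TaggedRead:
    """A demultiplexed read: cell label, UMI and trimmed genomic part."""

    cell: str
    umi: str
    sequence: str
    quality: str
    read_id: str

    def __post_init__(self) -> None:
        if len(self.umi) != UMI_LEN:
            raise ValueError(f"UMI must be {UMI_LEN} nt")
        if len(self.sequence) < 1:
            raise ValueError("empty genomic portion")


@dataclass
class DemuxResult:
    reads: List[TaggedRead]
    n_unassigned: int
    per_cell: Counter
    unassigned_reasons: Counter = field(default_factory=Counter)

    @property
    def n_assigned(self) -> int:
        return len(self.reads)

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned

    def report(self):
        import pandas as pd
        rows = [{"cell": c, "n_reads": n} for c, n in sorted(self.per_cell.items())]
        rows.append({"cell": "<unassigned>", "n_reads": self.n_unassigned})
        return pd.DataFrame(rows)


def match_barcode(observed: str, table: BarcodeTable, max_mismatch: int) -> Tuple[Optional[str], str]:
    """Return (cell label or None, reason).

    Assignment requires exactly one table barcode within ``max_mismatch``.
    """
    if max_mismatch == 0:
        cell = table.entries.get(observed)
        return (cell, "ok") if cell is not None else (None, "no_match")
    hits = [bc for bc in table.entries if hamming(observed, bc) <= max_mismatch]
    if len(hits) == 1:
        return table.entries[hits[0]], "ok"
    if len(hits) == 0:
        return None, "no_match"
    return None, "ambiguous"


def demultiplex_records(
    records: Iterable[Tuple[str, str, str]],
    barcodes: BarcodeTable,
    max_mismatch: int = 0,
) -> DemuxResult:
    """Demultiplex (read_id, sequence, quality) records.

    ``max_mismatch`` must be 0 (default; the assay expects the correct
    cell barcode) or 1.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    reads: List[TaggedRead] = []
    per_cell: Counter = Counter()
    reasons: Counter = Counter()
    n_unassigned = 0
    for rid, seq, qual in records:
        if len(seq) < _PREFIX_LEN + 1:
            n_unassigned += 1
            reasons["too_short"] += 1
            continue
        umi = seq[:UMI_LEN]
        bc = seq[UMI_LEN:_PREFIX_LEN]
        cell, reason = match_barcode(bc, barcodes, max_mismatch)
        if cell is None:
            n_unassigned += 1
            reasons[reason] += 1
            continue
        reads.append(TaggedRead(
            cell=cell, umi=umi,
            sequence=seq[_PREFIX_LEN:],
            quality=(qual or "")[_PREFIX_LEN:],
            read_id=rid))
        per_cell[cell] += 1
    return DemuxResult(reads=reads, n_unassigned=n_unassigned,
                       per_cell=per_cell, unassigned_reasons=reasons)


def demultiplex_fastq(
    fastq_in: str,
    barcodes: BarcodeTable,
    max_mismatch: int = 0,
    fastq_out: Optional[str] = None,
) -> DemuxResult:
    """Demultiplex a FASTQ file; optionally write tagged, trimmed FASTQ.

    Output headers carry ``CB:<cell> UMI:<umi>`` comments.  Running the
    demultiplexer on its own output is rejected (the prefix has already
    been trimmed).
    """
    def gen() -> Iterator[Tuple[str, str, str]]:
        for rid, comment, seq, qual in smio.read_fastq(fastq_in):
            if comment and "CB:" in comment and "UMI:" in comment:
                raise ValueError(
                    "input already demultiplexed (CB/UMI header tags present)")
            yield rid, seq, qual or "I" * len(seq)

    result = demultiplex_records(gen(), barcodes, max_mismatch)
    if fastq_out is not None:
        smio.write_fastq(
            ((f"{r.read_id} CB:{r.cell} UMI:{r.umi}", r.sequence, r.quality)
             for r in result.reads),
            fastq_out)
    return result
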