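"""Shared sequence helpers and geometry constants.

The MspJI cut geometry (16 bp downstream of the methylated cytosine, 4-nt
5' overhang) and the adapter layout (3-nt UMI followed by an 8-nt cell
barcode at the start of every read) are fixed properties of the assay and
are shared between the simulator and the site caller.
"""

from __future__ import annotations

import numpy as np

#: distance in bp from the methylated cytosine to the cut on its own strand
CUT_OFFSET = 16
#: length of the 5' overhang left by the enzyme (annotation only)
OVERHANG_LEN = 4
#: unique-molecule-identifier length at the read 5' end
UMI_LEN = 3
#: cell-barcode length following the UMI
BARCODE_LEN = 8

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# uint8 complement lookup for vectorised work on byte arrays
COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _COMP.items():
    COMP_TABLE[ord(_b)] = ord(_c)


def complement(base: str) -> str:
    return _COMP[base]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
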