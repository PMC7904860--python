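import numpy as np
import pytest

import strandmeth as sm
from strandmeth.simulate import STATE_5HMC, STATE_5MC, StrandStates


@pytest.fixture(scope="session")
def small_genome():
    """Two 5-kb chromosomes, no SNPs (haplotypes identical)."""
    return sm.make_genome(2, 5000, 0.5, 0.0, 7)


@pytest.fixture(scope="session")
def snp_genome():
    """Two 8-kb chromosomes with ~1% strain SNPs."""
    return sm.make_genome(2, 8000, 0.5, 0.01, 13)


def single_site_genome(ctx_after_c="G", r_base="A", length=200, c_pos=100):
    """A handcrafted one-chromosome genome with a single plus-strand C.

    The C sits at ``c_pos`` followed by ``ctx_after_c`` (the dinucleotide
    context) and ``r_base`` at +3 (the mCNNR recognition position).
    Everything else is A/T so no other cytosine exists on either strand.
    """
    seq = list("AT" * (length // 2))
    seq[c_pos] = "C"
    seq[c_pos + 1] = ctx_after_c
    seq[c_pos + 3] = r_base
    # keep surroundings free of accidental C/G
    for i in (c_pos - 1, c_pos + 2):
        if seq[i] in "CG":
            seq[i] = "A"
    return sm.SimGenome(chromosomes={"chr1": "".join(seq)}, snps=[], seed=0)


def single_site_truth(genome, state=STATE_5MC, strand="+", pos=100):
    """MethylomeTruth with exactly one cytosine in ``state``."""
    chrom = genome.chrom_names[0]
    seq = genome.haplotype(chrom, 1)
    if strand == "+":
        ctx = seq[pos + 1]
    else:
        ctx = {"A": "T", "C": "G", "G": "C", "T": "A"}[seq[pos - 1]]
    empty = StrandStates(np.array([], dtype=np.int64),
                         np.array([], dtype=np.uint8),
                         np.array([], dtype="U1"))
    states = {
        (chrom, 1, "+"): empty,
        (chrom, 1, "-"): empty,
        (chrom, 2, "+"): empty,
        (chrom, 2, "-"): empty,
    }
    states[(chrom, 1, strand)] = StrandStates(
        np.array([pos], dtype=np.int64),
        np.array([state], dtype=np.uint8),
        np.array([ctx], dtype="U1"))
    return sm.MethylomeTruth(cell_id=0, states=states,
                             parental={(chrom, 1): "+", (chrom, 2): "+"})
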