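"""Synthetic scMspJI-seq data generation.

Builds a small diploid genome with strain SNPs, lays down strand- and
allele-resolved cytosine states {C, 5mC, 5hmC} under a maintenance /
de-novo methylation model, digests the genome in silico with MspJI
(recognition mCNNR, cut 16 bp downstream of the methylated C, 4-nt 5'
overhang, 5hmC blocked by glucosylation), assembles barcoded reads with
the [UMI(3)][cell-barcode(8)][genomic] layout together with truth-aligned
SAM records, and simulates hairpin-bisulfite CpG-dyad read pairs.

All randomness flows through `numpy.random.default_rng` seeded from
explicit integers, so identical seeds give byte-identical output.

Methylation model
-----------------
Each CpG dyad has a "parental" strand, drawn once per (chromosome,
allele, cell) to mimic semiconservative replication: after one round of
replication every new double helix consists of one old (parental) strand
and one newly synthesised (daughter) strand, so hemimethylation is
coherent along a whole chromosome.  The parental-strand cytosine of a
dyad is methylated with probability ``m_parent``; given a methylated
parent, the daughter-strand cytosine is methylated with probability
``e_maint`` (the DNMT1 maintenance-efficiency axis).  CpA cytosines are
methylated independently per strand with probability ``d_cpa`` (de novo
activity; not a DNMT1 substrate).  Every methylated cytosine is then
converted to 5hmC with probability ``h_frac``; 5hmC is invisible to the
digest because glucosylation blocks the enzyme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .util import (
    BARCODE_LEN,
    COMP_TABLE,
    CUT_OFFSET,
    OVERHANG_LEN,
    UMI_LEN,
    revcomp,
    seq_to_bytes,
)

# cytosine state codes
STATE_C = 0
STATE_5MC = 1
STATE_5HMC = 2
STATE_NAMES = {STATE_C: "C", STATE_5MC: "5mC", STATE_5HMC: "5hmC"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_CHROM_LEN = 200


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenome:
    """A small diploid genome: reference sequences plus strain SNPs.

    Haplotype 1 is the reference itself; haplotype 2 carries the
    alternate base at every SNP (a hybrid-cross style background with
    one variant per site).
    """

    chromosomes: Dict[str, str]
    snps: List[Tuple[str, int, str, str]]  # (chrom, pos0, ref, alt)
    seed: int
    _hap2_cache: Dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: set = set()
        for chrom, pos0, ref, alt in self.snps:
            if (chrom, pos0) in seen:
                raise ValueError(f"duplicate SNP at {chrom}:{pos0}")
            seen.add((chrom, pos0))
            if ref == alt:
                raise ValueError("SNP alt base equals ref base")
            if self.chromosomes[chrom][pos0] != ref:
                raise ValueError("SNP ref base disagrees with sequence")

    def haplotype(self, chrom: str, allele: int) -> str:
        """Sequence of ``chrom`` on haplotype ``allele`` (1 or 2)."""
        if allele == 1:
            return self.chromosomes[chrom]
        if allele != 2:
            raise ValueError("allele must be 1 or 2")
        if chrom not in self._hap2_cache:
            seq = list(self.chromosomes[chrom])
            for c, pos0, _ref, alt in self.snps:
                if c == chrom:
                    seq[pos0] = alt
            self._hap2_cache[chrom] = "".join(seq)
        return self._hap2_cache[chrom]

    @property
    def chrom_names(self) -> List[str]:
        return list(self.chromosomes)


def make_genome(
    n_chrom: int,
    chrom_len: Union[int, Sequence[int]],
    gc: float,
    snp_rate: float,
    seed: int,
) -> SimGenome:
    """Generate a random diploid genome.

    Bases are i.i.d. with the requested GC fraction; SNP positions are
    Bernoulli(``snp_rate``) per site with a uniformly chosen alternate
    base, so the expected SNP count is ``snp_rate`` times the total
    length.  ``chrom_len`` may be a single length or one per chromosome
    (real karyotypes have very unequal chromosome sizes, which is what
    makes per-chromosome site counts covary between strands).
    Deterministic for a fixed ``seed``.
    """
    if isinstance(chrom_len, (int, np.integer)):
        lengths = [int(chrom_len)] * n_chrom
    else:
        lengths = [int(x) for x in chrom_len]
        if len(lengths) != n_chrom:
            raise ValueError("chrom_len sequence length must equal n_chrom")
    if min(lengths) < MIN_CHROM_LEN:
        raise ValueError(
            f"chrom_len must be >= {MIN_CHROM_LEN} to accommodate the "
            f"{CUT_OFFSET}-bp cut geometry plus a read"
        )
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    if not 0.0 <= snp_rate < 1.0:
        raise ValueError("snp_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    chromosomes: Dict[str, str] = {}
    snps: List[Tuple[str, int, str, str]] = []
    for i, clen in enumerate(lengths):
        name = f"chr{i + 1}"
        arr = rng.choice(_BASES, size=clen, p=p)
        seq = arr.tobytes().decode("ascii")
        chromosomes[name] = seq
        pos = np.flatnonzero(rng.random(clen) < snp_rate)
        for p0 in pos:
            ref = seq[p0]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[rng.integers(0, 3)]
            snps.append((name, int(p0), ref, alt))
    return SimGenome(chromosomes=chromosomes, snps=snps, seed=seed)


# ---------------------------------------------------------------------------
# methylome truth
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Parameters of the methylation / library model.

    Defaults describe a serum-grown mES-like condition: high CpG
    methylation with efficient DNMT1 maintenance, low de-novo CpA
    methylation, a small 5hmC fraction, partial molecule capture and
    amplification duplicates.
    """

    m_parent: float = 0.8       # P(parental-strand CpG methylated)
    e_maint: float = 0.95       # P(daughter methylated | parental 5mC)
    d_cpa: float = 0.02         # per-strand de novo CpA methylation
    h_frac: float = 0.05        # fraction of methylated sites that are 5hmC
    capture_eff: float = 0.5    # P(a true digestible 5mC yields a fragment)
    dup_rate: float = 1.0       # mean extra duplicate reads per molecule
    conv_err: float = 0.005     # hairpin bisulfite conversion error
    n_cells: int = 1
    barcodes: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m_parent", "e_maint", "d_cpa", "h_frac",
                     "capture_eff", "conv_err"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be non-negative")
        if not self.barcodes:
            self.barcodes = tuple(default_barcodes(max(self.n_cells, 1)))
        if self.n_cells > len(self.barcodes):
            raise ValueError("n_cells exceeds the number of barcodes")


def default_barcodes(n: int, seed: int = 17) -> List[str]:
    """Deterministic 8-nt cell barcodes with pairwise Hamming distance >= 2."""
    rng = np.random.default_rng(seed)
    out: List[str] = []
    while len(out) < n:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, BARCODE_LEN))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 2 for bc in out):
            out.append(cand)
    return out


@dataclass
class StrandStates:
    """Cytosine positions/states on one (chrom, allele, strand).

    ``pos`` holds reference-axis coordinates of the C base on that
    strand; ``state`` is the {C, 5mC, 5hmC} code; ``context`` is the
    base following the C in 5'->3' direction of the same strand, so
    'G' marks CpG, 'A' CpA, and so on.
    """

    pos: np.ndarray       # int64, sorted ascending
    state: np.ndarray     # uint8
    context: np.ndarray   # '<U1'


@dataclass
class MethylomeTruth:
    """Ground-truth methylome of one cell."""

    cell_id: int
    states: Dict[Tuple[str, int, str], StrandStates]  # (chrom, allele, strand)
    parental: Dict[Tuple[str, int], str]              # (chrom, allele) -> strand

    def sites_in_state(self, state: int) -> List[Tuple[str, int, str, int]]:
        """All (chrom, pos0, strand, allele) whose state equals ``state``."""
        out = []
        for (chrom, allele, strand), ss in self.states.items():
            for p in ss.pos[ss.state == state]:
                out.append((chrom, int(p), strand, allele))
        return out


def _strand_cytosines(b: np.ndarray, strand: str):
    """Positions and context bytes of cytosines on one strand of ``b``."""
    if strand == "+":
        pos = np.flatnonzero(b == ord("C"))
        ctx = np.full(pos.size, ord("N"), np.uint8)
        ok = pos + 1 < b.size
        ctx[ok] = b[pos[ok] + 1]
    else:
        pos = np.flatnonzero(b == ord("G"))
        ctx = np.full(pos.size, ord("N"), np.uint8)
        ok = pos - 1 >= 0
        ctx[ok] = COMP_TABLE[b[pos[ok] - 1]]
    return pos, ctx


def assign_methylome(
    genome: SimGenome,
    params: SimParams,
    cell_id: int,
    parental: Optional[Dict[Tuple[str, int], str]] = None,
) -> MethylomeTruth:
    """Draw a strand/allele-resolved methylome for one cell.

    ``parental`` optionally fixes the parental strand per (chromosome,
    allele); passing the strand-flipped map of another cell plants a
    sister pair (mirrored hemimethylation after a division without
    maintenance).
    """
    states: Dict[Tuple[str, int, str], StrandStates] = {}
    par: Dict[Tuple[str, int], str] = {}
    for ci, chrom in enumerate(genome.chrom_names):
        for allele in (1, 2):
            rng = np.random.default_rng([params.seed, cell_id, ci, allele])
            seq = genome.haplotype(chrom, allele)
            b = seq_to_bytes(seq)
            plus_pos, plus_ctx = _strand_cytosines(b, "+")
            minus_pos, minus_ctx = _strand_cytosines(b, "-")
            plus_state = np.zeros(plus_pos.size, np.uint8)
            minus_state = np.zeros(minus_pos.size, np.uint8)

            if parental is not None:
                p_strand = parental[(chrom, allele)]
            else:
                p_strand = "+" if rng.random() < 0.5 else "-"
            par[(chrom, allele)] = p_strand

            # CpG dyads: plus-strand C at i with G at i+1 pairs the
            # minus-strand C at i+1.
            dyad_plus_idx = np.flatnonzero(plus_ctx == ord("G"))
            dyad_pos = plus_pos[dyad_plus_idx]
            dyad_minus_idx = np.searchsorted(minus_pos, dyad_pos + 1)
            n_dyad = dyad_pos.size
            parent_meth = rng.random(n_dyad) < params.m_parent
            daughter_meth = parent_meth & (rng.random(n_dyad) < params.e_maint)
            if p_strand == "+":
                plus_m, minus_m = parent_meth, daughter_meth
            else:
                plus_m, minus_m = daughter_meth, parent_meth
            plus_state[dyad_plus_idx[plus_m]] = STATE_5MC
            minus_state[dyad_minus_idx[minus_m]] = STATE_5MC

            # de novo CpA methylation, independent per strand
            for pos_arr, ctx_arr, st_arr in (
                (plus_pos, plus_ctx, plus_state),
                (minus_pos, minus_ctx, minus_state),
            ):
                cpa = np.flatnonzero(ctx_arr == ord("A"))
                hit = cpa[rng.random(cpa.size) < params.d_cpa]
                st_arr[hit] = STATE_5MC

            # oxidation to 5hmC
            if params.h_frac > 0:
                for st_arr in (plus_state, minus_state):
                    meth = np.flatnonzero(st_arr == STATE_5MC)
                    st_arr[meth[rng.random(meth.size) < params.h_frac]] = STATE_5HMC

            states[(chrom, allele, "+")] = StrandStates(
                plus_pos, plus_state,
                plus_ctx.view("S1").astype("U1").reshape(plus_ctx.shape))
            states[(chrom, allele, "-")] = StrandStates(
                minus_pos, minus_state,
                minus_ctx.view("S1").astype("U1").reshape(minus_ctx.shape))
    return MethylomeTruth(cell_id=cell_id, states=states, parental=par)


# ---------------------------------------------------------------------------
# MspJI digest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """One captured MspJI cut: a 5mC in mCNNR context and its cut site."""

    chrom: str
    allele: int
    mC_pos0: int
    mC_strand: str
    cut_pos0: int
    cell_barcode: str
    umi: str
    overhang_len: int = OVERHANG_LEN


def digest_mspji(
    genome: SimGenome,
    truth: MethylomeTruth,
    capture_eff: float = 1.0,
    cell_barcode: str = "ACGTACGT",
    rng: Optional[np.random.Generator] = None,
) -> List[Fragment]:
    """In-silico MspJI digest of one cell's methylome.

    A fragment is emitted with probability ``capture_eff`` for every
    site whose state is 5mC and whose context matches mCNNR on its own
    strand (purine 3 bp downstream of the C).  5hmC sites are blocked
    by glucosylation and unmethylated sites are not recognised, so
    neither ever yields a fragment.  The cut lands exactly 16 nt
    downstream of the methylated cytosine on its strand; sites whose
    cut would fall outside the chromosome are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    frags: List[Fragment] = []
    for (chrom, allele, strand), ss in truth.states.items():
        b = seq_to_bytes(genome.haplotype(chrom, allele))
        meth = ss.pos[ss.state == STATE_5MC]
        if strand == "+":
            ok = meth + CUT_OFFSET < b.size
            meth = meth[ok]
            r = meth + 3
            ok = (r < b.size)
            meth = meth[ok]
            is_r = np.isin(b[meth + 3], [ord("A"), ord("G")])
            sites = meth[is_r]
            cuts = sites + CUT_OFFSET
        else:
            ok = meth - CUT_OFFSET >= 0
            meth = meth[ok]
            ok = meth - 3 >= 0
            meth = meth[ok]
            # purine on the minus strand = C or T on the reference
            is_r = np.isin(b[meth - 3], [ord("T"), ord("C")])
            sites = meth[is_r]
            cuts = sites - CUT_OFFSET
        keep = rng.random(sites.size) < capture_eff
        for p0, c0 in zip(sites[keep], cuts[keep]):
            umi = "".join("ACGT"[i] for i in rng.integers(0, 4, UMI_LEN))
            frags.append(Fragment(
                chrom=chrom, allele=allele, mC_pos0=int(p0),
                mC_strand=strand, cut_pos0=int(c0),
                cell_barcode=cell_barcode, umi=umi))
    frags.sort(key=lambda f: (f.chrom, f.mC_pos0, f.mC_strand, f.allele, f.umi))
    return frags


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    """A simulated read plus its truth alignment.

    ``sequence`` is the read as sequenced: UMI(3) + barcode(8) +
    genomic portion, where the genomic portion starts at the cut and
    runs back toward (and past) the methylated cytosine, i.e. the read
    maps antisense to the 5mC-bearing strand with its 5' genomic end at
    the cut coordinate.  ``genomic_fwd`` is the same genomic portion in
    reference-forward orientation (what a SAM record stores).
    """

    read_id: str
    sequence: str
    quality: str
    chrom: str
    ref_start0: int      # leftmost aligned base, 0-based
    reverse: bool        # True when the read maps to the minus strand
    genomic_fwd: str
    cell_barcode: str
    umi: str
    allele: int
    mC_pos0: int
    mC_strand: str


def emit_reads(
    fragments: Sequence[Fragment],
    genome: SimGenome,
    read_len: int = 75,
    dup_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[SimRead], List[Fragment]]:
    """Assemble sequencer-style reads from digest fragments.

    Each molecule is emitted ``1 + Poisson(dup_rate)`` times with an
    identical UMI and sequence (amplification duplicates).  Returns the
    reads and the fragments dropped because the genomic portion would
    run off the chromosome end (logged; only sites within a read length
    of a chromosome boundary can be affected).
    """
    min_len = UMI_LEN + BARCODE_LEN + 20
    if read_len < min_len:
        raise ValueError(f"read_len must be >= {min_len}")
    if rng is None:
        rng = np.random.default_rng(0)
    glen = read_len - UMI_LEN - BARCODE_LEN
    reads: List[SimRead] = []
    dropped: List[Fragment] = []
    for serial, frag in enumerate(fragments):
        hap = genome.haplotype(frag.chrom, frag.allele)
        if frag.mC_strand == "+":
            # cut right of the 5mC; read maps to the minus strand,
            # 5' genomic end at the cut
            start = frag.cut_pos0 - glen + 1
            if start < 0:
                dropped.append(frag)
                continue
            genomic_fwd = hap[start:frag.cut_pos0 + 1]
            read_genomic = revcomp(genomic_fwd)
            reverse = True
        else:
            start = frag.cut_pos0
            if start + glen > len(hap):
                dropped.append(frag)
                continue
            genomic_fwd = hap[start:start + glen]
            read_genomic = genomic_fwd
            reverse = False
        seq = frag.umi + frag.cell_barcode + read_genomic
        n_copies = 1 + int(rng.poisson(dup_rate))
        for copy in range(n_copies):
            reads.append(SimRead(
                read_id=f"sim.{frag.cell_barcode}.{serial}.{copy}",
                sequence=seq,
                quality="I" * len(seq),
                chrom=frag.chrom,
                ref_start0=start,
                reverse=reverse,
                genomic_fwd=genomic_fwd,
                cell_barcode=frag.cell_barcode,
                umi=frag.umi,
                allele=frag.allele,
                mC_pos0=frag.mC_pos0,
                mC_strand=frag.mC_strand,
            ))
    if dropped:
        logging.getLogger(__name__).info(
            "dropped %d fragments whose read would run off a chromosome end",
            len(dropped))
    return reads, dropped


def simulate_cell_reads(
    genome: SimGenome,
    params: SimParams,
    cell_id: int,
    read_len: int = 75,
    parental: Optional[Dict[Tuple[str, int], str]] = None,
) -> Tuple[MethylomeTruth, List[Fragment], List[SimRead]]:
    """Full per-cell simulation: methylome -> digest -> reads.

    The returned fragment list contains only emittable fragments (those
    whose read fits on the chromosome), so it matches the read set
    exactly.
    """
    truth = assign_methylome(genome, params, cell_id, parental=parental)
    barcode = params.barcodes[cell_id]
    rng = np.random.default_rng([params.seed, cell_id, 10_007])
    frags = digest_mspji(genome, truth, params.capture_eff, barcode, rng)
    reads, dropped = emit_reads(frags, genome, read_len, params.dup_rate, rng)
    if dropped:
        gone = set(dropped)
        frags = [f for f in frags if f not in gone]
    return truth, frags, reads


# ---------------------------------------------------------------------------
# hairpin bisulfite simulation
# ---------------------------------------------------------------------------

def simulate_hairpin(
    n_dyads: int,
    m_parent: float,
    e_maint: float,
    conv_err: float,
    seed: int,
) -> np.ndarray:
    """Simulate hairpin-bisulfite read-out of CpG dyads.

    Each dyad's true (top, bottom) methylation is drawn from the
    maintenance model (parental strand methylated with ``m_parent``,
    daughter copied with ``e_maint``, parental side randomised); the
    bisulfite read-out then flips each strand's methylated status
    independently with probability ``conv_err`` (failed conversion of an
    unmethylated C or over-conversion of a methylated C).

    Returns a boolean array of shape (n_dyads, 2): columns are the
    observed top/bottom methylation flags.
    """
    rng = np.random.default_rng(seed)
    parent = rng.random(n_dyads) < m_parent
    daughter = parent & (rng.random(n_dyads) < e_maint)
    parent_on_top = rng.random(n_dyads) < 0.5
    top = np.where(parent_on_top, parent, daughter)
    bottom = np.where(parent_on_top, daughter, parent)
    top = top ^ (rng.random(n_dyads) < conv_err)
    bottom = bottom ^ (rng.random(n_dyads) < conv_err)
    return np.column_stack([top, bottom])
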