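"""Hairpin-bisulfite CpG-dyad analysis.

A hairpin linker covalently joins the two strands of a fragment, so one
read pair reports the methylation status of both cytosines of each CpG
dyad.  Dyads are classified as symmetric (both methylated), hemi
(exactly one) or unmethylated, and the maintenance fraction — symmetric
dyads among dyads with at least one methylated cytosine — estimates the
DNMT1 maintenance efficiency.

Bisulfite read-out is imperfect: each strand's methylation flag flips
independently with probability ``conv_err`` (failed conversion of an
unmethylated C, or over-conversion of a methylated one).  That mixes
the three true classes through a known 3x3 confusion matrix, which
``correct_conversion`` inverts by method of moments, with a seeded
multinomial bootstrap for the confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DyadSummary:
    """Counts of CpG dyad classes from hairpin read pairs."""

    n_symmetric: int
    n_hemi: int
    n_unmethylated: int

    @property
    def total(self) -> int:
        return self.n_symmetric + self.n_hemi + self.n_unmethylated

    @property
    def frac_symmetric_of_methylated(self) -> float:
        """Symmetric fraction among dyads with >= 1 methylated cytosine."""
        denom = self.n_symmetric + self.n_hemi
        return self.n_symmetric / denom if denom else float("nan")

    @property
    def frac_symmetric_of_all(self) -> float:
        return self.n_symmetric / self.total if self.total else float("nan")

    def counts(self) -> np.ndarray:
        return np.array([self.n_symmetric, self.n_hemi, self.n_unmethylated])


@dataclass
class MaintenanceEstimate:
    """Conversion-error-corrected maintenance fraction with bootstrap CI."""

    corrected: float
    ci_low: float
    ci_high: float
    conv_err: float
    n_boot: int
    clipped: bool = False

    def summary(self) -> str:
        return (f"maintenance = {self.corrected:.4f} "
                f"[{self.ci_low:.4f}, {self.ci_high:.4f}] "
                f"(conv_err = {self.conv_err}, {self.n_boot} bootstrap resamples)")


def classify_dyads(observations: Iterable[Tuple[bool, bool]]) -> DyadSummary:
    """Classify (top, bottom) methylation flags into dyad classes.

    (True, True) -> symmetric; one True -> hemi; neither -> unmethylated.
    Accepts any iterable of flag pairs, including the (n, 2) arrays from
    the hairpin simulator.
    """
    arr = np.asarray(list(observations) if not isinstance(observations, np.ndarray)
                     else observations, dtype=bool)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("observations must be pairs of flags")
    n_meth = arr.sum(axis=1)
    return DyadSummary(
        n_symmetric=int((n_meth == 2).sum()),
        n_hemi=int((n_meth == 1).sum()),
        n_unmethylated=int((n_meth == 0).sum()),
    )


def _confusion_matrix(conv_err: float) -> np.ndarray:
    """Observed-class probabilities given true class, order (sym, hemi, unmeth).

    Each strand flips independently with probability ``conv_err``.
    """
    e = conv_err
    q = 1.0 - e
    return np.array([
        #  true sym   true hemi      true unmeth
        [q * q,       e * q,         e * e],       # observed sym
        [2 * e * q,   q * q + e * e, 2 * e * q],   # observed hemi
        [e * e,       e * q,         q * q],       # observed unmeth
    ])


def _corrected_fraction(counts: np.ndarray, A_inv: np.ndarray) -> Tuple[float, bool]:
    total = counts.sum()
    est = A_inv @ (counts / total)
    clipped = bool((est < 0).any() or (est > 1).any())
    est = np.clip(est, 0.0, None)
    s, h, _u = est
    if s + h == 0:
        return float("nan"), clipped
    raw = s / (s + h)
    if raw < 0 or raw > 1:
        clipped = True
    return float(np.clip(raw, 0.0, 1.0)), clipped


def correct_conversion(
    summary: DyadSummary,
    conv_err: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> MaintenanceEstimate:
    """Invert the conversion-error confusion to estimate maintenance.

    Method of moments: observed class frequencies equal
    ``A(conv_err) @ true frequencies``; solving for the true vector and
    clipping to [0, 1] gives the corrected symmetric-of-methylated
    fraction.  With ``conv_err = 0`` this is exactly the raw fraction.
    The CI is a seeded multinomial bootstrap (percentile 2.5/97.5).
    """
    if not 0.0 <= conv_err < 0.5:
        raise ValueError("conv_err must be in [0, 0.5)")
    counts = summary.counts()
    if summary.n_symmetric + summary.n_hemi == 0:
        raise ValueError(
            "no methylated dyads observed; maintenance fraction undefined")
    A_inv = np.linalg.inv(_confusion_matrix(conv_err))
    point, clipped = _corrected_fraction(counts.astype(float), A_inv)
    if clipped:
        logger.warning("corrected class frequencies clipped into [0, 1]")

    total = counts.sum()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    resamples = rng.multinomial(total, counts / total, size=n_boot)
    for b in range(n_boot):
        boots[b], _ = _corrected_fraction(resamples[b].astype(float), A_inv)
    ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    # the percentile interval is widened to contain the point estimate
    ci_low = min(float(ci_low), point)
    ci_high = max(float(ci_high), point)
    return MaintenanceEstimate(corrected=point, ci_low=ci_low, ci_high=ci_high,
                               conv_err=conv_err, n_boot=n_boot, clipped=clipped)


def estimate_maintenance(
    observations: Iterable[Tuple[bool, bool]],
    conv_err: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[DyadSummary, MaintenanceEstimate]:
    """Convenience: classify dyads and correct for conversion error."""
    summary = classify_dyads(observations)
    return summary, correct_conversion(summary, conv_err, n_boot=n_boot, seed=seed)
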