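"""Outgroup f3 and f4 statistics with block-jackknife standard errors.

f3(O; A, B) = E[(p_O - p_A)(p_O - p_B)] measures the drift shared by A and
B after their divergence from the outgroup O: with a fixed distant
outgroup, a larger outgroup-f3 means a closer pair.  f4(A, B; C, D) =
E[(p_A - p_B)(p_C - p_D)] is the classic treeness/asymmetry test; it is
zero when (A, B) and (C, D) are symmetric pairs, and antisymmetric in each
pair.

Estimates are plain means of the per-SNP terms over complete cases (sites
where every population has a called frequency).  Uncertainty comes from a
delete-one block jackknife over contiguous SNP blocks (default 500 SNPs;
SNP-count blocks are used because the synthetic panels carry no genetic
map).  No within-population heterozygosity correction is applied by
default: outgroup-f3 *rankings* are unaffected by the shared offset, and
the correction can be enabled with ``h_correction=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["FStatResult", "block_jackknife", "outgroup_f3", "f4"]


@dataclass
class FStatResult:
    """One f-statistic with its jackknife uncertainty."""

    statistic: str
    populations: tuple[str, ...]
    estimate: float
    jackknife_se: float
    n_snps_used: int
    n_blocks: int

    @property
    def z(self) -> float:
        if self.jackknife_se == 0 or not np.isfinite(self.jackknife_se):
            return float("nan")
        return self.estimate / self.jackknife_se

    def summary(self) -> str:
        pops = ", ".join(self.populations)
        z = self.z
        return (
            f"{self.statistic}({pops}) = {self.estimate:+.6f} "
            f"+/- {self.jackknife_se:.6f}  Z = "
            + (f"{z:+.2f}" if np.isfinite(z) else "undefined")
            + f"  ({self.n_snps_used} SNPs, {self.n_blocks} blocks)"
        )


def block_jackknife(terms: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Mean of ``terms`` and its delete-one-block jackknife SE.

    Blocks are contiguous runs of ``block_size`` terms (the last block may
    be shorter).  With fewer than 2 blocks the SE is NaN.  The estimate is
    always the plain mean, independent of the block partition.
    """
    terms = np.asarray(terms, dtype=float)
    n = len(terms)
    if n == 0:
        raise InvalidParameterError("no terms to jackknife")
    if block_size < 1:
        raise InvalidParameterError("block_size must be >= 1")
    estimate = float(terms.mean())
    total = terms.sum()
    starts = np.arange(0, n, block_size)
    n_blocks = len(starts)
    if n_blocks < 2:
        return estimate, float("nan"), n_blocks
    loo = np.empty(n_blocks)
    for j, s in enumerate(starts):
        block = terms[s : s + block_size]
        loo[j] = (total - block.sum()) / (n - len(block))
    # standard delete-one jackknife variance over the leave-block-out means
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return estimate, se, n_blocks


def _complete(*freqs) -> np.ndarray:
    arrays = [np.asarray(f, dtype=float) for f in freqs]
    if len({a.shape for a in arrays}) != 1:
        raise InvalidParameterError("frequency vectors differ in length")
    mask = np.ones(arrays[0].shape, dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    if not mask.any():
        raise InvalidParameterError("no SNP has all populations called")
    return mask


def outgroup_f3(
    p_outgroup,
    p_a,
    p_b,
    block_size_snps: int = 500,
    populations: tuple[str, str, str] = ("O", "A", "B"),
    h_correction=None,
) -> FStatResult:
    """Outgroup f3(O; A, B) with block-jackknife SE.

    ``h_correction`` optionally subtracts a per-SNP bias term (e.g. the
    outgroup heterozygosity estimate divided by its sample size); pass a
    vector aligned with the frequencies, or None (default) for the raw
    statistic.
    """
    mask = _complete(p_outgroup, p_a, p_b)
    o = np.asarray(p_outgroup, dtype=float)[mask]
    a = np.asarray(p_a, dtype=float)[mask]
    b = np.asarray(p_b, dtype=float)[mask]
    terms = (o - a) * (o - b)
    if h_correction is not None:
        terms = terms - np.asarray(h_correction, dtype=float)[mask]
    est, se, n_blocks = block_jackknife(terms, block_size_snps)
    return FStatResult("f3", populations, est, se, int(mask.sum()), n_blocks)


def f4(
    p_a,
    p_b,
    p_c,
    p_d,
    block_size_snps: int = 500,
    populations: tuple[str, str, str, str] = ("A", "B", "C", "D"),
) -> FStatResult:
    """f4(A, B; C, D) with block-jackknife SE."""
    mask = _complete(p_a, p_b, p_c, p_d)
    a = np.asarray(p_a, dtype=float)[mask]
    b = np.asarray(p_b, dtype=float)[mask]
    c = np.asarray(p_c, dtype=float)[mask]
    d = np.asarray(p_d, dtype=float)[mask]
    terms = (a - b) * (c - d)
    est, se, n_blocks = block_jackknife(terms, block_size_snps)
    return FStatResult("f4", populations, est, se, int(mask.sum()), n_blocks)
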