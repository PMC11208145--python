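"""Three-population locus-specific branch length (LSBL) selection scan.

For three populations A, B, C the pairwise F_ST distances d_AB, d_AC and
d_BC at a SNP decompose into population-specific branch lengths

    x = (d_AB + d_AC - d_BC) / 2      (branch leading to A)
    y = (d_AB + d_BC - d_AC) / 2      (branch leading to B)
    z = (d_AC + d_BC - d_AB) / 2      (branch leading to C)

so that x + y + z = (d_AB + d_AC + d_BC) / 2 exactly.  A large branch for
one population flags an allele-frequency shift specific to that lineage, a
candidate signal of positive selection.  Candidates are taken from the
empirical tails (top 0.5% and 0.1%) of each branch's distribution.

F_ST is estimated per SNP with Hudson's ratio estimator with sample-size
correction (robust to unequal sample sizes; a Weir-Cockerham variant is
available behind ``estimator="wc"``).  Negative per-SNP distances are
clipped to zero before decomposition - a negative distance has no
interpretation as a branch length - while the raw values are kept in the
output table.

The scan applies the standard site filters first: autosomes only, pooled
minor-allele frequency >= 0.01, individuals with more than 97% missing
data removed, then LD pruning with a 200-SNP window sliding by 25 at
r^2 > 0.4 (greedy removal, keeping the higher-MAF SNP of each pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .freq import PopulationFrequencies, population_frequencies
from .io import MISSING, GenotypeMatrix

__all__ = [
    "site_filters",
    "ld_prune",
    "pairwise_fst",
    "lsbl_decompose",
    "empirical_outliers",
    "LSBLScan",
    "LSBLResults",
]


# ---------------------------------------------------------------------------
# Site and individual filters
# ---------------------------------------------------------------------------


def site_filters(
    matrix: GenotypeMatrix,
    maf_min: float = 0.01,
    max_ind_missing: float = 0.97,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the scan's QC filters.

    Autosomes only; individuals with a missing fraction strictly greater
    than ``max_ind_missing`` are dropped; SNPs whose pooled minor-allele
    frequency (over the retained individuals) is strictly below ``maf_min``
    are dropped (monomorphic sites always fail).  Returns the filtered
    matrix and a report of what was removed.
    """
    m = matrix.take_snps(np.flatnonzero(matrix.autosomal_mask()))
    n_sex_snps = matrix.n_snps - m.n_snps
    miss_frac = 1.0 - m.non_missing_counts() / max(m.n_snps, 1)
    keep_ind = miss_frac <= max_ind_missing
    dropped_ind = [l for l, k in zip(m.labels, keep_ind) if not k]
    m = m.take_individuals(np.flatnonzero(keep_ind))
    pooled = population_frequencies(m)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(pooled.freq, 1.0 - pooled.freq)
    keep_snp = np.nan_to_num(maf, nan=-1.0) >= maf_min
    n_maf_dropped = int((~keep_snp).sum())
    m = m.take_snps(np.flatnonzero(keep_snp))
    if m.n_snps == 0:
        warnings.warn("site filters removed every SNP", stacklevel=2)
    return m, {
        "n_sex_chromosome_snps_removed": int(n_sex_snps),
        "individuals_removed": dropped_ind,
        "n_low_maf_snps_removed": n_maf_dropped,
    }


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """r^2 between SNP call vectors (rows) over jointly called individuals.

    Calls are treated as haploid 0/1 alleles (composite correlation); pairs
    with no variance in the joint overlap get r^2 = 0.
    """
    obs = (calls != MISSING).astype(np.float64)
    alt = (calls == 1).astype(np.float64)
    n = obs @ obs.T
    sx = alt @ obs.T  # sum of x over the joint mask; asymmetric
    sxy = alt @ alt.T
    cov = n * sxy - sx * sx.T
    varx = n * sx - sx**2
    vary = varx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((varx > 0) & (vary > 0), cov**2 / (varx * vary), 0.0)
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window_snps: int = 200,
    step_snps: int = 25,
    r2_max: float = 0.4,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Within each window of ``window_snps`` SNPs (advanced by ``step_snps``,
    per chromosome, positions sorted), every pair with r^2 strictly above
    ``r2_max`` loses one member: the SNP with the lower pooled MAF, with
    ties broken by dropping the later position.  Sweeps repeat until no SNP
    is removed, so the result is invariant to repeated application.
    """
    pooled = population_frequencies(matrix)
    with np.errstate(invalid="ignore"):
        maf = np.nan_to_num(np.minimum(pooled.freq, 1.0 - pooled.freq), nan=0.0)
    retained = np.ones(matrix.n_snps, dtype=bool)
    chroms = matrix.snps["chrom"].to_numpy()
    changed = True
    while changed:
        changed = False
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero((chroms == chrom) & retained)
            start = 0
            while start < len(idx):
                window = idx[start : start + window_snps]
                live = window[retained[window]]
                if len(live) > 1:
                    r2 = _pairwise_r2(matrix.calls[:, live].T)
                    k = len(live)
                    for a in range(k):
                        if not retained[live[a]]:
                            continue
                        for b in range(a + 1, k):
                            if not retained[live[b]]:
                                continue
                            if r2[a, b] > r2_max:
                                ia, ib = live[a], live[b]
                                if maf[ia] < maf[ib]:
                                    drop = ia
                                elif maf[ib] < maf[ia]:
                                    drop = ib
                                else:  # tie -> later position
                                    drop = max(ia, ib)
                                retained[drop] = False
                                changed = True
                                if drop == ia:
                                    break
                if start + window_snps >= len(idx):
                    break
                start += step_snps
    return np.flatnonzero(retained)


# ---------------------------------------------------------------------------
# F_ST and the branch decomposition
# ---------------------------------------------------------------------------


def pairwise_fst(
    p1, n1, p2, n2, estimator: str = "hudson"
) -> np.ndarray:
    """Per-SNP pairwise F_ST distance between two populations.

    Hudson's estimator with sample-size correction::

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    ``n`` counts called alleles (one per individual for pseudo-haploid
    data).  Sites with n <= 1 in either population, or an undefined
    denominator, return NaN.  The raw value may be negative; callers clip
    for branch computation.  ``estimator="wc"`` switches to a
    Weir-Cockerham-style haploid variant.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 > 1) & (n2 > 1) & np.isfinite(p1) & np.isfinite(p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
        elif estimator == "wc":
            # haploid analogue of the Weir-Cockerham variance decomposition
            nbar = (n1 + n2) / 2
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))  # = 2 n1 n2 / (n1+n2)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
            num = s2 - (pbar * (1 - pbar) - s2 / 2) / (nc - 1)
            den = pbar * (1 - pbar) + s2 / 4
        else:
            raise InvalidParameterError(f"unknown F_ST estimator {estimator!r}")
        d = np.where(ok & (den > 0), num / den, np.nan)
    return d


def lsbl_decompose(d_ab, d_ac, d_bc) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Branch lengths (x, y, z) from the three pairwise distances.

    Exact arithmetic; negative branches are reported raw.
    """
    d_ab = np.asarray(d_ab, dtype=float)
    d_ac = np.asarray(d_ac, dtype=float)
    d_bc = np.asarray(d_bc, dtype=float)
    x = (d_ab + d_ac - d_bc) / 2
    y = (d_ab + d_bc - d_ac) / 2
    z = (d_ac + d_bc - d_ab) / 2
    return x, y, z


def empirical_outliers(
    values: np.ndarray, tails: tuple[float, ...] = (0.005, 0.001)
) -> dict[float, np.ndarray]:
    """Boolean flags for the empirical upper tail(s) of a branch distribution.

    For tail fraction t over n finite values the threshold is the
    ceil(n*t)-th largest value; every value >= threshold is flagged, so
    ties at the threshold are all included and smaller tails are nested
    inside larger ones.  A degenerate all-equal distribution flags every
    value, with a warning.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = int(finite.sum())
    out: dict[float, np.ndarray] = {}
    for tail in tails:
        flags = np.zeros(values.shape, dtype=bool)
        if n:
            k = max(1, int(np.ceil(n * tail)))
            threshold = np.sort(values[finite])[-k]
            flags[finite] = values[finite] >= threshold
            if flags[finite].all() and n > k:
                warnings.warn(
                    f"degenerate branch distribution: all {n} values tie at "
                    f"the {tail:.3%} threshold",
                    stacklevel=2,
                )
        out[tail] = flags
    return out


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------


class LSBLScan:
    """LSBL scan over three populations.

    Construct either from three :class:`PopulationFrequencies` (plus an
    optional SNP table), or from a genotype matrix with group labels via
    :meth:`from_matrix`, which applies the site filters and LD pruning
    before counting alleles.
    """

    def __init__(
        self,
        pop_a: PopulationFrequencies,
        pop_b: PopulationFrequencies,
        pop_c: PopulationFrequencies,
        snps: pd.DataFrame | None = None,
        tails: tuple[float, ...] = (0.005, 0.001),
        estimator: str = "hudson",
    ) -> None:
        if not len(pop_a) == len(pop_b) == len(pop_c):
            raise InvalidParameterError("population frequency sets differ in length")
        self.pops = (pop_a, pop_b, pop_c)
        self.snps = snps
        self.tails = tuple(sorted(tails, reverse=True))
        self.estimator = estimator

    @classmethod
    def from_matrix(
        cls,
        matrix: GenotypeMatrix,
        groups: tuple[str, str, str],
        maf_min: float = 0.01,
        max_ind_missing: float = 0.97,
        prune: bool = True,
        window_snps: int = 200,
        step_snps: int = 25,
        r2_max: float = 0.4,
        tails: tuple[float, ...] = (0.005, 0.001),
        estimator: str = "hudson",
    ) -> "LSBLScan":
        filtered, _ = site_filters(matrix, maf_min, max_ind_missing)
        if prune:
            filtered = filtered.take_snps(
                ld_prune(filtered, window_snps, step_snps, r2_max)
            )
        pops = [population_frequencies(filtered, g) for g in groups]
        return cls(*pops, snps=filtered.snps, tails=tails, estimator=estimator)

    def fit(self) -> "LSBLResults":
        a, b, c = self.pops
        d_ab = pairwise_fst(a.freq, a.totals, b.freq, b.totals, self.estimator)
        d_ac = pairwise_fst(a.freq, a.totals, c.freq, c.totals, self.estimator)
        d_bc = pairwise_fst(b.freq, b.totals, c.freq, c.totals, self.estimator)
        x, y, z = lsbl_decompose(
            np.clip(d_ab, 0, None), np.clip(d_ac, 0, None), np.clip(d_bc, 0, None)
        )
        table = pd.DataFrame(
            {
                "d_AB": d_ab,
                "d_AC": d_ac,
                "d_BC": d_bc,
                "x": x,
                "y": y,
                "z": z,
            }
        )
        if self.snps is not None:
            table.insert(0, "chrom", self.snps["chrom"].to_numpy())
            table.insert(1, "pos", self.snps["pos"].to_numpy())
        for branch in ("x", "y", "z"):
            flags = empirical_outliers(table[branch].to_numpy(), self.tails)
            col = np.full(len(table), "none", dtype=object)
            for tail in self.tails:  # larger tail first, finer overwrites
                col[flags[tail]] = f"top{tail * 100:g}"
            table[f"tail_{branch}"] = col
        table["tail_flag"] = table["tail_x"]
        return LSBLResults(table=table, model=self)


@dataclass
class LSBLResults:
    """Per-SNP distances, branch lengths and empirical tail flags."""

    table: pd.DataFrame
    model: LSBLScan = field(repr=False)

    def outliers(self, branch: str = "x", tail: float = 0.005) -> pd.DataFrame:
        name = f"top{tail * 100:g}"
        col = self.table[f"tail_{branch}"]
        finer = [f"top{t * 100:g}" for t in self.model.tails if t <= tail]
        return self.table[col.isin([name, *finer])]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Locus-specific branch length scan",
            "=" * 40,
            f"SNPs scored:      {len(t)}",
            f"estimator:        {self.model.estimator}",
        ]
        for branch in ("x", "y", "z"):
            vals = t[branch].dropna()
            lines.append(
                f"branch {branch}: mean {vals.mean():.4f}  max {vals.max():.4f}  "
                f"top0.5% n={int((t[f'tail_{branch}'] != 'none').sum())}"
            )
        return "\n".join(lines)

    def plot_manhattan(self, branch: str = "x", ax=None):
        """Manhattan plot of one branch with the empirical tail thresholds."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        vals = self.table[branch].to_numpy()
        ax.scatter(np.arange(len(vals)), vals, s=4, c="grey")
        finite = vals[np.isfinite(vals)]
        for tail, color in zip(self.model.tails, ("tab:blue", "tab:red")):
            k = max(1, int(np.ceil(len(finite) * tail)))
            ax.axhline(np.sort(finite)[-k], color=color, lw=1,
                       label=f"top {tail:.1%}")
        ax.set_xlabel("SNP index")
        ax.set_ylabel(f"branch {branch}")
        ax.legend(frameon=False)
        return ax
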