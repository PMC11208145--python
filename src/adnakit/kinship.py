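"""Pairwise-mismatch-rate kinship classification for pseudo-haploid data.

The pairwise mismatch rate (PMR) of two individuals is the fraction of
jointly called autosomal SNPs at which their pseudo-haploid alleles differ.
Under Hardy-Weinberg sampling the expected per-SNP mismatch probability is
``2p(1-p)`` for an unrelated pair and exactly half that for two draws from
one diploid genome (a monozygotic twin pair, or a duplicated sample), with
first- and second-degree relatives falling at 3/4 and 7/8 of the unrelated
expectation.  Dividing each pair's PMR by a cohort background (the median
PMR over all valid pairs, robust as long as relatives are a minority)
therefore yields normalized values near 1.0, 0.875, 0.75 and 0.5, and pairs
are binned at the midpoints between those expectations.

Usage follows the model/results convention::

    result = PairwiseMismatch(matrix).fit()
    result.pairs            # per-pair table
    result.summary()        # text report
    result.relatedness_summary()

The module-level functions expose each stage individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError
from .io import MISSING, GenotypeMatrix

#: Midpoints between expected normalized PMRs (0.5, 0.75, 0.875, 1.0).
DEFAULT_BINS = (0.625, 0.8125, 0.90625)

CLOSE_DEGREES = ("identical", "first", "second")


def pairwise_mismatch_rate(
    matrix: GenotypeMatrix,
    min_overlap: int = 5000,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """PMR for every pair of individuals.

    Only jointly non-missing SNPs count; X/Y SNPs are excluded by default
    (an all-male cohort would bias X comparisons).  Pairs with overlap below
    ``min_overlap`` are retained in the table but flagged invalid and left
    unclassified downstream.

    Returns a DataFrame with columns ``sample_i``, ``sample_j`` (i < j in
    matrix order), ``overlap``, ``mismatches``, ``pmr``, ``valid``.
    """
    if matrix.n_individuals < 2:
        raise DegenerateCohortError("need at least 2 individuals for PMR")
    calls = matrix.calls
    if autosomes_only:
        calls = calls[:, matrix.autosomal_mask()]
    observed = (calls != MISSING).astype(np.float64)
    alt = (calls == 1).astype(np.float64)
    ref = observed - alt
    overlap = observed @ observed.T
    mismatches = alt @ ref.T + ref @ alt.T
    labels = matrix.labels
    iu, ju = np.triu_indices(len(labels), k=1)
    ov = overlap[iu, ju]
    mm = mismatches[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        pmr = np.where(ov > 0, mm / ov, np.nan)
    df = pd.DataFrame(
        {
            "sample_i": [labels[i] for i in iu],
            "sample_j": [labels[j] for j in ju],
            "overlap": ov.astype(int),
            "mismatches": mm.astype(int),
            "pmr": pmr,
            "valid": ov >= min_overlap,
        }
    )
    if not df["valid"].any():
        warnings.warn("no pair reaches the minimum SNP overlap", stacklevel=2)
    return df


def normalize_background(pairs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide each pair's PMR by the cohort background (median valid PMR).

    The median is robust provided relatives are a minority of pairs (the
    documented failure mode is a cohort dominated by relatives, where the
    background is dragged down and all normalized values inflate).

    Raises
    ------
    DegenerateCohortError
        With fewer than 3 valid pairs, or a zero background.
    """
    valid = pairs.loc[pairs["valid"], "pmr"].dropna()
    if len(valid) < 3:
        raise DegenerateCohortError(
            f"background needs >= 3 valid pairs, found {len(valid)}"
        )
    background = float(valid.median())
    if background == 0:
        raise DegenerateCohortError("zero background PMR; cohort degenerate")
    out = pairs.copy()
    out["normalized_pmr"] = out["pmr"] / background
    return out, background


def classify_pairs(
    pairs: pd.DataFrame, bins: tuple[float, float, float] = DEFAULT_BINS
) -> pd.DataFrame:
    """Bin normalized PMR into identical / first / second / unrelated.

    Invalid pairs (insufficient overlap) are reported as ``unclassified``.
    """
    b1, b2, b3 = bins
    out = pairs.copy()

    def one(v: float, valid: bool) -> str:
        if not valid or np.isnan(v):
            return "unclassified"
        if v < b1:
            return "identical"
        if v < b2:
            return "first"
        if v < b3:
            return "second"
        return "unrelated"

    out["degree"] = [
        one(v, ok) for v, ok in zip(out["normalized_pmr"], out["valid"])
    ]
    return out


def summarize_relatedness(pairs: pd.DataFrame) -> dict:
    """Counts of close pairs (degree <= second) and individuals involved."""
    close = pairs[pairs["degree"].isin(CLOSE_DEGREES)]
    individuals = set(close["sample_i"]) | set(close["sample_j"])
    return {
        "n_close_pairs": int(len(close)),
        "n_identical_pairs": int((close["degree"] == "identical").sum()),
        "n_individuals_in_close_pairs": len(individuals),
    }


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------


class PairwiseMismatch:
    """PMR kinship model over a pseudo-haploid genotype matrix."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        min_overlap: int = 5000,
        bins: tuple[float, float, float] = DEFAULT_BINS,
        autosomes_only: bool = True,
    ) -> None:
        self.matrix = matrix
        self.min_overlap = min_overlap
        self.bins = bins
        self.autosomes_only = autosomes_only

    def fit(self) -> "KinshipResults":
        pairs = pairwise_mismatch_rate(
            self.matrix, self.min_overlap, self.autosomes_only
        )
        pairs, background = normalize_background(pairs)
        pairs = classify_pairs(pairs, self.bins)
        return KinshipResults(pairs=pairs, background=background, model=self)


@dataclass
class KinshipResults:
    """Fitted PMR classification: per-pair table plus the cohort background."""

    pairs: pd.DataFrame
    background: float
    model: PairwiseMismatch = field(repr=False)

    def relatedness_summary(self) -> dict:
        return summarize_relatedness(self.pairs)

    def close_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["degree"].isin(CLOSE_DEGREES)].reset_index(
            drop=True
        )

    def summary(self) -> str:
        s = self.relatedness_summary()
        lines = [
            "Pairwise mismatch rate kinship classification",
            "=" * 45,
            f"individuals:                {self.model.matrix.n_individuals}",
            f"pairs evaluated:            {len(self.pairs)}",
            f"background PMR (median):    {self.background:.4f}",
            f"close pairs (degree <= 2):  {s['n_close_pairs']}",
            f"  identical (MZ/duplicate): {s['n_identical_pairs']}",
            f"individuals in close pairs: {s['n_individuals_in_close_pairs']}",
            "",
        ]
        close = self.close_pairs()
        if len(close):
            lines.append("pair                     overlap    PMR    norm  degree")
            for r in close.itertuples(index=False):
                lines.append(
                    f"{r.sample_i}-{r.sample_j:<15} {r.overlap:8d} "
                    f"{r.pmr:7.4f} {r.normalized_pmr:6.3f}  {r.degree}"
                )
        return "\n".join(lines)

    def plot(self, threshold: float = 0.20, ax=None):
        """PMR dot plot of pairs under ``threshold`` (the display filter
        used for relatedness figures); close pairs highlighted."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        shown = self.pairs[self.pairs["pmr"] < threshold]
        close = shown["degree"].isin(CLOSE_DEGREES)
        ax.scatter(
            np.flatnonzero(~close.to_numpy()),
            shown.loc[~close, "pmr"],
            marker="^",
            c="black",
            s=12,
            label="unrelated",
        )
        ax.scatter(
            np.flatnonzero(close.to_numpy()),
            shown.loc[close, "pmr"],
            marker="D",
            facecolors="none",
            edgecolors="tab:red",
            s=24,
            label="close pair",
        )
        ax.set_xlabel("pair index")
        ax.set_ylabel("pairwise mismatch rate")
        ax.legend(frameon=False)
        return ax
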