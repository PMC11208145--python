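"""Per-population allele-frequency containers.

Pseudo-haploid data contribute one called allele per individual per SNP, so
the "allele total" at a SNP is the number of non-missing individuals, not
twice that number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix


@dataclass
class PopulationFrequencies:
    """Alternate-allele counts and called-allele totals per SNP."""

    counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if self.counts.shape != self.totals.shape:
            raise ValueError("counts and totals must have equal shape")
        if np.any(self.counts > self.totals):
            raise ValueError("counts may not exceed totals")

    @property
    def freq(self) -> np.ndarray:
        """Frequency estimate count/total; NaN where no alleles were called."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.counts / self.totals, np.nan)

    def __len__(self) -> int:
        return len(self.counts)


def population_frequencies(
    matrix: GenotypeMatrix, group: str | None = None
) -> PopulationFrequencies:
    """Alt-allele counts/totals over the individuals of ``group``.

    With ``group=None`` all individuals are pooled.
    """
    if group is None:
        sub = matrix.calls
    else:
        idx = (matrix.individuals["group"] == group).to_numpy()
        if not idx.any():
            raise ValueError(f"no individuals in group {group!r}")
        sub = matrix.calls[idx]
    called = sub != MISSING
    return PopulationFrequencies(
        counts=(sub == 1).sum(axis=0), totals=called.sum(axis=0)
    )
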