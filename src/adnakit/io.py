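"""Reading and writing the file formats the pipeline touches.

The canonical in-memory representation is a pseudo-haploid
:class:`GenotypeMatrix`: one allele call per individual per SNP, encoded as
``0`` (reference), ``1`` (alternate) or ``-1`` (missing).  Pseudo-haploid
random-draw genotypes are the standard representation for low-coverage
ancient-DNA capture data, and every downstream statistic in this package is
defined on them; diploid genotypes only exist transiently inside the
synthetic-cohort generator.

Supported formats
-----------------
* EIGENSTRAT ``.geno``/``.snp``/``.ind`` triplets (fixed-width genotype
  digits, whitespace-delimited metadata).  Genotype digits count copies of
  the *reference* allele (``0``, ``1``, ``2``) with ``9`` for missing; a
  pseudo-haploid dataset therefore contains only ``0``/``2``/``9``.  A ``1``
  (heterozygote) in a declared pseudo-haploid dataset is demoted to missing
  with a warning rather than rejected, because merges with diploid reference
  panels occur in practice.
* Coverage TSV: ``sample``, ``chromosome_class`` (``autosome``/``X``/``Y``),
  ``sites_covered``, ``total_reads``.
* HLA genotype CSV (``sample``, ``locus``, ``allele1``, ``allele2``) and
  phased haplotype CSV (``sample``, ``haplotype_index``, ``locus``,
  ``allele``).
* Isotope CSV (``sample``, ``d13C_permil``, ``d15N_permil``,
  ``collagen_yield_pct``, ``CN_ratio``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

#: Sentinel for a missing pseudo-haploid call.
MISSING: int = -1

_AUTOSOMES = tuple(str(c) for c in range(1, 23))

_CHROM_ORDER = {c: i for i, c in enumerate(_AUTOSOMES + ("X", "Y"))}


def normalize_chromosome(label) -> str:
    """Map numeric sex-chromosome labels onto X/Y (EIGENSTRAT uses 23/24)."""
    s = str(label).strip()
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    return s


@dataclass
class GenotypeMatrix:
    """Pseudo-haploid calls for N individuals at M SNPs.

    Attributes
    ----------
    calls
        ``(N, M)`` int8 array with values in ``{0, 1, MISSING}``.
    individuals
        DataFrame with columns ``label``, ``sex`` (male/female/unknown) and
        ``group`` (cohort label).
    snps
        DataFrame with columns ``id``, ``chrom``, ``pos``, ``ref``, ``alt``,
        sorted by (chromosome, position).
    """

    calls: np.ndarray
    individuals: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise FormatError("calls must be a 2-D array")
        n, m = self.calls.shape
        if len(self.individuals) != n:
            raise FormatError(
                f"{len(self.individuals)} individual records for {n} call rows"
            )
        if len(self.snps) != m:
            raise FormatError(f"{len(self.snps)} SNP records for {m} call columns")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise FormatError("calls must be 0, 1 or missing (-1)")
        self.individuals = self.individuals.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.snps["chrom"] = self.snps["chrom"].map(normalize_chromosome)
        order = np.lexsort(
            (
                self.snps["pos"].to_numpy(),
                self.snps["chrom"].map(lambda c: _CHROM_ORDER.get(c, 99)).to_numpy(),
            )
        )
        if not np.array_equal(order, np.arange(m)):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def labels(self) -> list[str]:
        return self.individuals["label"].tolist()

    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over SNP columns selecting chromosomes 1-22."""
        return self.snps["chrom"].isin(_AUTOSOMES).to_numpy()

    def non_missing_counts(self) -> np.ndarray:
        """Number of called (non-missing) SNPs per individual."""
        return (self.calls != MISSING).sum(axis=1)

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index],
            self.individuals.iloc[index].reset_index(drop=True),
            self.snps.copy(),
        )

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.individuals.copy(),
            self.snps.iloc[index].reset_index(drop=True),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.individuals["label"].tolist() == other.individuals["label"].tolist()
            and self.snps[["id", "chrom", "pos", "ref", "alt"]].equals(
                other.snps[["id", "chrom", "pos", "ref", "alt"]]
            )
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

_SEX_TO_EIG = {"male": "M", "female": "F", "unknown": "U"}
_EIG_TO_SEX = {"M": "male", "F": "female", "U": "unknown"}


def _with_ext(prefix: Path, ext: str) -> Path:
    # append rather than substitute, so dotted prefixes survive
    return prefix.parent / f"{prefix.name}.{ext}"


def read_eigenstrat(prefix: str | Path) -> GenotypeMatrix:
    """Read an EIGENSTRAT ``geno``/``snp``/``ind`` triplet.

    Genotype digits are interpreted as reference-allele counts; in a
    pseudo-haploid dataset ``2`` maps to call 0 (reference), ``0`` to call 1
    (alternate) and ``9`` to missing.  A diploid heterozygote digit ``1`` is
    set to missing with a warning.

    Raises
    ------
    FormatError
        If any geno line length disagrees with the number of individuals, or
        the number of geno lines disagrees with the snp file.
    """
    prefix = Path(prefix)
    ind = pd.read_csv(
        _with_ext(prefix, "ind"),
        sep=r"\s+",
        header=None,
        names=["label", "sex", "group"],
        dtype=str,
    )
    ind["sex"] = ind["sex"].map(lambda s: _EIG_TO_SEX.get(s, "unknown"))
    snp = pd.read_csv(
        _with_ext(prefix, "snp"),
        sep=r"\s+",
        header=None,
        names=["id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"id": str, "chrom": str, "ref": str, "alt": str},
    )
    snp["pos"] = snp["pos"].astype(int)
    snps = snp[["id", "chrom", "pos", "ref", "alt"]].copy()

    n = len(ind)
    rows: list[np.ndarray] = []
    het_seen = 0
    lut = np.full(128, 127, dtype=np.int8)
    lut[ord("2")] = 0  # two reference copies -> reference call
    lut[ord("0")] = 1  # zero reference copies -> alternate call
    lut[ord("9")] = MISSING
    lut[ord("1")] = 100  # heterozygote sentinel, resolved below
    with open(_with_ext(prefix, "geno")) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n:
                raise FormatError(
                    f"{prefix}.geno line {lineno}: {len(line)} genotypes "
                    f"for {n} individuals"
                )
            codes = lut[np.frombuffer(line.encode(), dtype=np.uint8)]
            if (codes == 127).any():
                raise FormatError(f"{prefix}.geno line {lineno}: invalid digit")
            het = codes == 100
            if het.any():
                het_seen += int(het.sum())
                codes[het] = MISSING
            rows.append(codes)
    if len(rows) != len(snps):
        raise FormatError(
            f"{prefix}.geno has {len(rows)} SNP lines but {prefix}.snp has {len(snps)}"
        )
    if het_seen:
        warnings.warn(
            f"{het_seen} heterozygote calls in pseudo-haploid dataset set to missing",
            stacklevel=2,
        )
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(calls, ind[["label", "sex", "group"]], snps)


def write_eigenstrat(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``matrix`` as an EIGENSTRAT triplet (inverse of the reader)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = np.full(matrix.calls.shape, ord("9"), dtype=np.uint8)
    out[matrix.calls == 0] = ord("2")
    out[matrix.calls == 1] = ord("0")
    with open(_with_ext(prefix, "geno"), "w") as fh:
        for col in out.T:  # one line per SNP
            fh.write(col.tobytes().decode() + "\n")
    with open(_with_ext(prefix, "snp"), "w") as fh:
        for rec in matrix.snps.itertuples(index=False):
            fh.write(
                f"{rec.id}\t{rec.chrom}\t0.0\t{rec.pos}\t{rec.ref}\t{rec.alt}\n"
            )
    with open(_with_ext(prefix, "ind"), "w") as fh:
        for rec in matrix.individuals.itertuples(index=False):
            fh.write(f"{rec.label}\t{_SEX_TO_EIG.get(rec.sex, 'U')}\t{rec.group}\n")


# ---------------------------------------------------------------------------
# Individual retention filter
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Outcome of the individual-retention filter."""

    min_snps: int
    kept: list[str] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)


def filter_individuals(
    matrix: GenotypeMatrix, min_snps: int = 20_000
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals unless they retain *strictly more than* ``min_snps``
    non-missing calls.

    The strict inequality matters: an individual with exactly ``min_snps``
    covered SNPs is dropped.  Returns the filtered matrix and a report with
    the dropped labels and their call counts.
    """
    counts = matrix.non_missing_counts()
    keep = counts > min_snps
    report = FilterReport(
        min_snps=min_snps,
        kept=[l for l, k in zip(matrix.labels, keep) if k],
        dropped={l: int(c) for l, c, k in zip(matrix.labels, counts, keep) if not k},
    )
    return matrix.take_individuals(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Tabular side-files
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["sample", "chromosome_class", "sites_covered", "total_reads"]


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"coverage table missing columns: {sorted(missing)}")
    return df


def write_coverage_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COVERAGE_COLUMNS)


def read_hla_genotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    need = {"sample", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise FormatError(f"HLA genotype table needs columns {sorted(need)}")
    return df


def read_haplotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"haplotype_index": int})
    need = {"sample", "haplotype_index", "locus", "allele"}
    if not need <= set(df.columns):
        raise FormatError(f"haplotype table needs columns {sorted(need)}")
    return df


ISOTOPE_COLUMNS = [
    "sample",
    "d13C_permil",
    "d15N_permil",
    "collagen_yield_pct",
    "CN_ratio",
]


def read_isotopes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ISOTOPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"isotope table missing columns: {sorted(missing)}")
    return df
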