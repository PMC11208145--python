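"""Synthetic pseudo-haploid cohorts with known ground truth.

Every downstream stage of the pipeline (kinship, sexing, selection scan,
HLA comparison) can be exercised end-to-end on cohorts generated here, with
a :class:`TruthTable` recording the planted relatedness degrees and sexes.

The generator emulates the structure of a 1240K-style ancient-DNA capture
experiment:

* ancestral allele frequencies drawn from a U-shaped Beta(0.8, 0.8) prior,
  resembling the site-frequency spectrum of an ascertained SNP panel;
* founders drawn under Hardy-Weinberg equilibrium, children by fair
  Mendelian transmission, monozygotic twins sharing one diploid genome;
* pseudo-haploid random-draw genotyping with independent per-call
  missingness (optionally scaled per individual to model variable
  preservation);
* per-chromosome-class read counts for genetic sexing, Poisson-distributed
  around the karyotype expectation.

It does NOT simulate sequence reads, post-mortem damage, contamination or
realistic linkage disequilibrium; see docs/methods.md for what that implies
about test coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, PedigreeError
from .freq import PopulationFrequencies
from .io import MISSING, GenotypeMatrix

__all__ = [
    "PedigreeSpec",
    "CohortConfig",
    "TruthTable",
    "generate_allele_frequencies",
    "drop_alleles",
    "generate_pedigree_cohort",
    "pseudo_haploidize",
    "synthetic_snp_table",
    "make_genotype_matrix",
    "simulate_sex_coverage",
    "simulate_hla_cohorts",
    "simulate_selection_shift",
    "chultun_like_pedigree",
    "chultun_like_cohort",
    "DEFAULT_SITE_COUNTS",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Pedigrees and truth tables
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSpec:
    """A pedigree as founders, (child, parent1, parent2) triples and MZ pairs.

    ``relations`` must be listed so that every parent is a founder or an
    earlier child.  Members of ``mz_twin_pairs`` are (template, copy): the
    copy label must not appear anywhere else and receives an identical
    diploid genome.  ``sampled`` restricts the generated cohort to a subset
    of members (latent parents stay ungenotyped); default is every member.
    """

    founders: list[str]
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    mz_twin_pairs: list[tuple[str, str]] = field(default_factory=list)
    sampled: list[str] | None = None
    sexes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = list(self.founders)
        defined = set(ordered)
        if len(defined) != len(ordered):
            raise PedigreeError("duplicate founder labels")
        for child, p1, p2 in self.relations:
            if child in defined:
                raise PedigreeError(f"label {child!r} defined twice")
            for p in (p1, p2):
                if p not in defined:
                    raise PedigreeError(
                        f"parent {p!r} of {child!r} is not a founder or earlier child"
                    )
            defined.add(child)
            ordered.append(child)
        for t1, t2 in self.mz_twin_pairs:
            if t1 not in defined:
                raise PedigreeError(f"twin template {t1!r} undefined")
            if t2 in defined:
                raise PedigreeError(f"twin copy {t2!r} must be a fresh label")
            defined.add(t2)
            ordered.append(t2)
        self._members = ordered
        if self.sampled is not None:
            unknown = set(self.sampled) - defined
            if unknown:
                raise PedigreeError(f"sampled labels not in pedigree: {sorted(unknown)}")

    @property
    def members(self) -> list[str]:
        return list(self._members)

    @property
    def cohort(self) -> list[str]:
        return list(self.sampled) if self.sampled is not None else self.members

    def sex_of(self, label: str) -> str:
        return self.sexes.get(label, "male")


def kinship_coefficients(ped: PedigreeSpec) -> pd.DataFrame:
    """Exact kinship coefficients phi for every pair of pedigree members.

    Founders are unrelated and non-inbred; the usual recursion
    phi(i,j) = (phi(f_i,j)+phi(m_i,j))/2 and
    phi(i,i) = 1/2 (1 + phi(f_i,m_i)) applies in pedigree order.  An MZ twin
    copy inherits its template's full row, and phi(template, copy) equals
    phi(template, template) because the two share one genome.
    """
    order = list(ped.founders) + [c for c, _, _ in ped.relations]
    idx = {l: i for i, l in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for f in ped.founders:
        phi[idx[f], idx[f]] = 0.5
    for child, p1, p2 in ped.relations:
        i, a, b = idx[child], idx[p1], idx[p2]
        for j in range(n):
            if j == i:
                continue
            phi[i, j] = phi[j, i] = 0.5 * (phi[a, j] + phi[b, j])
        phi[i, i] = 0.5 * (1.0 + phi[a, b])
    labels = list(order)
    out = phi
    for t1, t2 in ped.mz_twin_pairs:
        i = idx[t1]
        row = out[i].copy()
        out = np.pad(out, ((0, 1), (0, 1)))
        out[-1, :-1] = row
        out[:-1, -1] = row
        out[-1, -1] = out[i, i]
        out[i, -1] = out[-1, i] = out[i, i]  # shared genome
        labels.append(t2)
        idx[t2] = len(labels) - 1
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class TruthTable:
    """Planted ground truth: pair -> degree and individual -> sex."""

    degrees: dict[tuple[str, str], str]
    sexes: dict[str, str]

    def degree(self, a: str, b: str) -> str:
        return self.degrees.get(tuple(sorted((a, b))), "unrelated")

    def close_pairs(self) -> list[tuple[str, str]]:
        return [p for p, d in self.degrees.items() if d in ("identical", "first", "second")]

    def identical_pairs(self) -> list[tuple[str, str]]:
        return [p for p, d in self.degrees.items() if d == "identical"]

    def individuals_in_close_pairs(self) -> set[str]:
        return {x for p in self.close_pairs() for x in p}


def truth_from_pedigree(ped: PedigreeSpec) -> TruthTable:
    """Derive pair degrees from exact kinship coefficients.

    identical: MZ pair (phi = 1/2); first: phi = 1/4 (parent-offspring or
    full sibs); second: phi = 1/8 (half sibs, avuncular, grandparental);
    anything lower is recorded as unrelated.
    """
    phi = kinship_coefficients(ped)
    cohort = ped.cohort
    mz = {tuple(sorted(p)) for p in ped.mz_twin_pairs}
    degrees: dict[tuple[str, str], str] = {}
    for a, b in itertools.combinations(sorted(cohort), 2):
        v = phi.loc[a, b]
        if (a, b) in mz or np.isclose(v, 0.5):
            d = "identical"
        elif np.isclose(v, 0.25):
            d = "first"
        elif np.isclose(v, 0.125):
            d = "second"
        else:
            d = "unrelated"
        if d != "unrelated":
            degrees[(a, b)] = d
    return TruthTable(degrees=degrees, sexes={l: ped.sex_of(l) for l in cohort})


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort draw."""

    n_individuals: int
    n_snps: int
    pedigree: PedigreeSpec
    freq_prior_alpha: float = 0.8
    freq_prior_beta: float = 0.8
    missing_rate: float = 0.1
    seed: int = 0
    #: optional per-individual multiplier on missing_rate (variable preservation)
    missing_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise InvalidParameterError("n_individuals and n_snps must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise InvalidParameterError("missing_rate must be in [0, 1)")
        if len(self.pedigree.cohort) != self.n_individuals:
            raise InvalidParameterError(
                f"pedigree cohort has {len(self.pedigree.cohort)} members, "
                f"config says {self.n_individuals}"
            )


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------


def generate_allele_frequencies(
    n_snps: int, alpha: float = 0.8, beta: float = 0.8, seed=0
) -> np.ndarray:
    """Draw SNP allele frequencies from Beta(alpha, beta), strictly in (0, 1).

    Boundary draws (possible at extreme shapes through floating-point
    underflow) are resampled so monomorphic sites never enter a cohort.
    """
    if n_snps < 1:
        raise InvalidParameterError("n_snps must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise InvalidParameterError("Beta shapes must be > 0")
    rng = _rng(seed)
    p = rng.beta(alpha, beta, size=n_snps)
    bad = (p <= 0.0) | (p >= 1.0)
    while bad.any():
        p[bad] = rng.beta(alpha, beta, size=int(bad.sum()))
        bad = (p <= 0.0) | (p >= 1.0)
    return p


def drop_alleles(
    ped: PedigreeSpec,
    founder_haplotypes: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Transmit alleles down the pedigree (gene dropping).

    ``founder_haplotypes`` maps each founder to a ``(2, M)`` array; the
    values are opaque (0/1 alleles for genotype simulation, or unique
    integer tags when the caller wants to trace identity-by-descent).  Each
    child receives one uniformly chosen allele per parent per site, drawn
    independently across sites; an MZ twin copy duplicates its template.
    """
    haps = {f: np.asarray(founder_haplotypes[f]) for f in ped.founders}
    m = next(iter(haps.values())).shape[1] if haps else 0
    cols = np.arange(m)
    for child, p1, p2 in ped.relations:
        h = np.empty((2, m), dtype=haps[p1].dtype)
        h[0] = haps[p1][rng.integers(0, 2, size=m), cols]
        h[1] = haps[p2][rng.integers(0, 2, size=m), cols]
        haps[child] = h
    for t1, t2 in ped.mz_twin_pairs:
        haps[t2] = haps[t1].copy()
    return haps


def generate_pedigree_cohort(
    config: CohortConfig, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, list[str], TruthTable]:
    """Diploid genotypes (0/1/2 alt-allele dosage) for the sampled cohort.

    Founders are drawn under Hardy-Weinberg equilibrium from the frequency
    vector (generated from the config's Beta prior when not supplied);
    children follow fair Mendelian transmission.  Returns the dosage matrix,
    the cohort labels (in pedigree-cohort order) and the truth table.
    """
    rng = _rng(config.seed)
    if freqs is None:
        freqs = generate_allele_frequencies(
            config.n_snps, config.freq_prior_alpha, config.freq_prior_beta, rng
        )
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != config.n_snps:
        raise InvalidParameterError("frequency vector length != n_snps")
    ped = config.pedigree
    founder_haps = {
        f: (rng.random((2, config.n_snps)) < freqs).astype(np.int8)
        for f in ped.founders
    }
    haps = drop_alleles(ped, founder_haps, rng)
    labels = ped.cohort
    diploid = np.stack([haps[l].sum(axis=0) for l in labels]).astype(np.int8)
    return diploid, labels, truth_from_pedigree(ped)


def pseudo_haploidize(
    diploid: np.ndarray,
    missing_rate: float = 0.0,
    seed=0,
    missing_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-haploid random draw: one allele per site, plus random dropout.

    For dosage ``g`` the drawn allele is alternate with probability ``g/2``
    (deterministic for homozygotes, a fair coin for heterozygotes).  Sites
    are then set to missing independently with probability ``missing_rate``
    (optionally scaled per individual by ``missing_scale``).
    """
    if not 0 <= missing_rate < 1:
        raise InvalidParameterError("missing_rate must be in [0, 1)")
    diploid = np.asarray(diploid)
    if not np.isin(diploid, (0, 1, 2)).all():
        raise InvalidParameterError("diploid dosages must be 0, 1 or 2")
    rng = _rng(seed)
    calls = (rng.random(diploid.shape) < diploid / 2.0).astype(np.int8)
    rate = np.full(diploid.shape[0], missing_rate)
    if missing_scale is not None:
        rate = np.clip(rate * np.asarray(missing_scale, dtype=float), 0.0, 0.999)
    drop = rng.random(diploid.shape) < rate[:, None]
    calls[drop] = MISSING
    return calls


def synthetic_snp_table(n_snps: int) -> pd.DataFrame:
    """Deterministic autosomal SNP metadata: 22 contiguous chromosome blocks."""
    chroms = np.array_split(np.arange(n_snps), 22)
    rows = []
    for c, block in enumerate(chroms, start=1):
        for k, i in enumerate(block):
            rows.append((f"snp{i:07d}", str(c), (k + 1) * 1000, "A", "G"))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])


def make_genotype_matrix(
    calls: np.ndarray,
    labels: list[str],
    group: str = "SIM",
    sexes: dict[str, str] | None = None,
    snps: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Wrap raw pseudo-haploid calls into a :class:`GenotypeMatrix`."""
    sexes = sexes or {}
    ind = pd.DataFrame(
        {
            "label": labels,
            "sex": [sexes.get(l, "unknown") for l in labels],
            "group": group,
        }
    )
    if snps is None:
        snps = synthetic_snp_table(calls.shape[1])
    return GenotypeMatrix(calls, ind, snps)


# ---------------------------------------------------------------------------
# Coverage profiles for sexing
# ---------------------------------------------------------------------------

#: 1240K-like targeted-site counts per chromosome class.
DEFAULT_SITE_COUNTS = {"autosome": 1_150_000, "X": 49_000, "Y": 32_000}


def simulate_sex_coverage(
    sexes,
    mean_depth: float,
    site_counts: dict[str, int] | None = None,
    spurious_y_rate: float = 0.01,
    seed=0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual read totals on autosomal, X and Y targeted SNPs.

    Autosomal totals are Poisson(sites x depth).  Males carry one X and one
    Y, so their X and Y per-site depth is half the autosomal depth; females
    carry two X (full depth) and no Y apart from a small spurious-mapping
    rate (default 1% of autosomal depth).

    ``sexes`` is a sequence of "male"/"female" labels, one per individual.
    """
    if mean_depth <= 0:
        raise InvalidParameterError("mean_depth must be > 0")
    sites = dict(DEFAULT_SITE_COUNTS if site_counts is None else site_counts)
    rng = _rng(seed)
    sexes = list(sexes)
    if labels is None:
        labels = [f"S{i + 1:03d}" for i in range(len(sexes))]
    rows = []
    for label, sex in zip(labels, sexes):
        if sex == "male":
            rates = {"autosome": mean_depth, "X": mean_depth / 2, "Y": mean_depth / 2}
        elif sex == "female":
            rates = {
                "autosome": mean_depth,
                "X": mean_depth,
                "Y": spurious_y_rate * mean_depth,
            }
        else:
            raise InvalidParameterError(f"unknown sex label {sex!r}")
        for cls in ("autosome", "X", "Y"):
            reads = int(rng.poisson(sites[cls] * rates[cls]))
            rows.append((label, cls, sites[cls], reads))
    return pd.DataFrame(
        rows, columns=["sample", "chromosome_class", "sites_covered", "total_reads"]
    )


# ---------------------------------------------------------------------------
# HLA cohorts
# ---------------------------------------------------------------------------


def _shift_pool(pool: pd.DataFrame, shift_spec: dict) -> pd.DataFrame:
    """Re-weight a haplotype pool so chosen alleles hit shifted frequencies.

    ``shift_spec`` maps (locus, allele) -> delta on the allele frequency.
    Haplotypes carrying the allele are scaled by target/current and the rest
    by (1-target)/(1-current), which preserves the relative composition
    within carriers and non-carriers.
    """
    out = pool.copy()
    for (locus, allele), delta in shift_spec.items():
        carrier = out[locus] == allele
        current = out.loc[carrier, "freq"].sum()
        if not 0 < current < 1:
            raise InvalidParameterError(
                f"allele {allele!r} at {locus!r} has degenerate pool frequency {current}"
            )
        target = current + delta
        if not 0 < target < 1:
            raise InvalidParameterError(
                f"shifted frequency for {locus}:{allele} is {target}, outside (0, 1)"
            )
        out.loc[carrier, "freq"] *= target / current
        out.loc[~carrier, "freq"] *= (1 - target) / (1 - current)
    if not np.isclose(out["freq"].sum(), 1.0):
        raise InvalidParameterError("shifted pool frequencies do not normalize")
    if (out["freq"] < 0).any():
        raise InvalidParameterError("shifted pool contains negative frequencies")
    return out


def simulate_hla_cohorts(
    pool: pd.DataFrame,
    shift_spec: dict | None,
    n1: int,
    n2: int,
    seed=0,
    cohort_names: tuple[str, str] = ("COHORT1", "COHORT2"),
) -> dict[str, pd.DataFrame]:
    """Draw two diploid HLA cohorts from a phased haplotype pool.

    ``pool`` has one row per distinct multi-locus haplotype, one column per
    HLA locus plus a ``freq`` column summing to 1.  Cohort 2 is drawn from
    the pool re-weighted by ``shift_spec``.  Each individual receives two
    independent haplotypes; phase is retained in the haplotype tables.

    Returns ``{"genotypes1", "genotypes2", "haplotypes1", "haplotypes2"}``.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("cohort sizes must be >= 1")
    if not np.isclose(pool["freq"].sum(), 1.0):
        raise InvalidParameterError("pool frequencies must sum to 1")
    loci = [c for c in pool.columns if c != "freq"]
    rng = _rng(seed)
    pools = {
        cohort_names[0]: pool,
        cohort_names[1]: _shift_pool(pool, shift_spec) if shift_spec else pool,
    }
    out: dict[str, pd.DataFrame] = {}
    for k, (name, n) in enumerate(zip(cohort_names, (n1, n2)), start=1):
        cp = pools[name]
        draws = rng.choice(len(cp), size=(n, 2), p=cp["freq"].to_numpy())
        geno_rows, hap_rows = [], []
        for i in range(n):
            sample = f"{name}_{i + 1:03d}"
            h = [cp.iloc[draws[i, 0]], cp.iloc[draws[i, 1]]]
            for locus in loci:
                geno_rows.append((sample, locus, h[0][locus], h[1][locus]))
                for hap_index in (1, 2):
                    hap_rows.append((sample, hap_index, locus, h[hap_index - 1][locus]))
        out[f"genotypes{k}"] = pd.DataFrame(
            geno_rows, columns=["sample", "locus", "allele1", "allele2"]
        )
        out[f"haplotypes{k}"] = pd.DataFrame(
            hap_rows, columns=["sample", "haplotype_index", "locus", "allele"]
        )
    return out


# ---------------------------------------------------------------------------
# Three-population frequency sets for the selection scan
# ---------------------------------------------------------------------------


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1 / (1 + np.exp(-x))


def simulate_selection_shift(
    base_freqs: np.ndarray,
    selected_indices,
    shift: float,
    drift_sd: float = 0.05,
    n_alleles: tuple[int, int, int] = (100, 100, 100),
    seed=0,
) -> dict[str, PopulationFrequencies]:
    """Three population count sets with selection planted in population A.

    All three populations drift independently from ``base_freqs`` on the
    logit scale (Gaussian with sd ``drift_sd``); population A is
    additionally shifted by ``shift`` on the frequency scale at
    ``selected_indices`` only (clamped inside (0, 1)).  Counts are binomial
    draws of ``n_alleles`` called alleles per population.
    """
    base = np.asarray(base_freqs, dtype=float)
    if np.any((base <= 0) | (base >= 1)):
        raise InvalidParameterError("base frequencies must lie strictly in (0, 1)")
    if not np.isfinite(shift):
        raise InvalidParameterError("shift must be finite")
    sel = np.asarray(list(selected_indices), dtype=int)
    rng = _rng(seed)
    eps = 1e-4
    out: dict[str, PopulationFrequencies] = {}
    for pop, n in zip("ABC", n_alleles):
        p = _expit(_logit(base) + rng.normal(0.0, drift_sd, size=base.shape))
        if pop == "A" and sel.size:
            p[sel] = np.clip(p[sel] + shift, eps, 1 - eps)
        counts = rng.binomial(n, p)
        out[pop] = PopulationFrequencies(counts=counts, totals=np.full(base.shape, n))
    return out


# ---------------------------------------------------------------------------
# The packaged chultun-like fixture
# ---------------------------------------------------------------------------


def chultun_like_pedigree(n_individuals: int = 64) -> PedigreeSpec:
    """The packaged relatedness fixture: 64 sampled subadults.

    Structure (latent parents are never genotyped):

    * one isolated MZ twin pair;
    * a connected family of four: a second MZ twin pair, a half sibling of
      the twins through one parent, and a further half sibling of that
      individual through their other parent (so the outermost individual is
      unrelated to the twins);
    * three mutually unrelated full-sibling pairs;
    * a four-individual half-sibling chain (consecutive members share one
      parent, non-consecutive members are unrelated);
    * unrelated singletons filling the cohort to ``n_individuals``.

    By construction this yields exactly 11 pairs of degree <= 2 (2 of them
    identical) over 16 distinct individuals.
    """
    if n_individuals < 16:
        raise InvalidParameterError("fixture needs at least 16 individuals")
    lab = [f"IND{i + 1:03d}" for i in range(n_individuals)]
    latent = [f"PAR{i + 1:02d}" for i in range(17)]
    P = dict(zip(range(1, 18), latent))
    relations = [
        # isolated twins IND001/IND002 (template IND001)
        ("IND001", P[1], P[2]),
        # connected family: twins IND003/IND004, half-sib IND005 via P[3],
        # half-sib-of-half-sib IND006 via P[5]
        ("IND003", P[3], P[4]),
        ("IND005", P[3], P[5]),
        ("IND006", P[5], P[6]),
        # three unrelated full-sib pairs
        ("IND007", P[7], P[8]),
        ("IND008", P[7], P[8]),
        ("IND009", P[9], P[10]),
        ("IND010", P[9], P[10]),
        ("IND011", P[11], P[12]),
        ("IND012", P[11], P[12]),
        # four-individual half-sib chain through shared parents 13..17
        ("IND013", P[13], P[14]),
        ("IND014", P[14], P[15]),
        ("IND015", P[15], P[16]),
        ("IND016", P[16], P[17]),
    ]
    singletons = lab[16:]
    return PedigreeSpec(
        founders=latent + singletons,
        relations=relations,
        mz_twin_pairs=[("IND001", "IND002"), ("IND003", "IND004")],
        sampled=lab,
        sexes={l: "male" for l in lab},
    )


def chultun_like_cohort(
    n_snps: int = 100_000,
    missing_rate: float = 0.10,
    seed: int = 1,
    alpha: float = 0.8,
    beta: float = 0.8,
    group: str = "CH",
) -> tuple[GenotypeMatrix, TruthTable]:
    """Generate the packaged 64-individual fixture as a genotype matrix."""
    ped = chultun_like_pedigree()
    # two independent sub-seeds: genotype generation and pseudo-haploid draw
    sub = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    config = CohortConfig(
        n_individuals=len(ped.cohort),
        n_snps=n_snps,
        pedigree=ped,
        freq_prior_alpha=alpha,
        freq_prior_beta=beta,
        missing_rate=missing_rate,
        seed=int(sub[0]),
    )
    diploid, labels, truth = generate_pedigree_cohort(config, freqs=None)
    calls = pseudo_haploidize(diploid, missing_rate, seed=int(sub[1]))
    matrix = make_genotype_matrix(calls, labels, group=group, sexes=truth.sexes)
    return matrix, truth
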