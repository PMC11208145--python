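"""Bone-collagen stable-isotope QC, summaries and diet-similarity testing.

delta13C (permil vs VPDB) tracks the dietary carbon source (C3 vs C4
plants and marine input); delta15N (permil vs AIR) tracks trophic level.
Collagen preservation QC follows the standard archaeological criteria:
collagen yield strictly greater than 1% by weight, and atomic C:N ratio
inside [2.9, 3.6] (both bounds inclusive).

``related_pair_similarity`` formalizes "related individuals ate alike":
the observed mean pairwise Euclidean distance in (d13C, d15N) space among
genetically close pairs is compared against a null built by permuting
sample labels over the isotope records; the one-sided, add-one-corrected
p value is the probability of a null mean distance at least as small.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["collagen_qc", "cohort_summary", "related_pair_similarity"]

YIELD_MIN_PCT = 1.0
CN_RANGE = (2.9, 3.6)


def collagen_qc(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``qc_pass`` and ``qc_reason`` columns to an isotope table.

    Pass requires collagen_yield_pct > 1 (strict) and 2.9 <= CN_ratio <= 3.6
    (inclusive).  Records with a missing yield or C:N are unevaluable and
    fail with reason ``"unevaluable"``.
    """
    out = records.copy()
    y = pd.to_numeric(out["collagen_yield_pct"], errors="coerce")
    cn = pd.to_numeric(out["CN_ratio"], errors="coerce")
    reasons = []
    passes = []
    for yi, ci in zip(y, cn):
        if pd.isna(yi) or pd.isna(ci):
            passes.append(False)
            reasons.append("unevaluable")
            continue
        why = []
        if not yi > YIELD_MIN_PCT:
            why.append("yield")
        if not CN_RANGE[0] <= ci <= CN_RANGE[1]:
            why.append("C:N")
        passes.append(not why)
        reasons.append(",".join(why) if why else "")
    out["qc_pass"] = passes
    out["qc_reason"] = reasons
    return out


def cohort_summary(records: pd.DataFrame, column: str) -> dict:
    """{n, min, max, mean, sd} of one isotope column over QC-passing records.

    ``sd`` is the sample standard deviation (n-1 denominator).  Returns an
    empty dict when no record passes QC.
    """
    if "qc_pass" not in records.columns:
        records = collagen_qc(records)
    vals = pd.to_numeric(
        records.loc[records["qc_pass"], column], errors="coerce"
    ).dropna()
    if vals.empty:
        return {}
    return {
        "n": int(len(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }


def related_pair_similarity(
    records: pd.DataFrame,
    close_pairs,
    n_perm: int = 10_000,
    seed: int = 0,
    weights: tuple[float, float] = (1.0, 1.0),
) -> dict:
    """Permutation test: do close relatives have more similar diets?

    ``close_pairs`` is an iterable of (sample_a, sample_b) labels.  The
    statistic is the mean pairwise Euclidean distance in weighted
    (d13C, d15N) space over the close pairs with isotope data for both
    members.  The null permutes which sample carries which isotope record;
    the one-sided p value is add-one corrected:
    ``p = (1 + #{null <= observed}) / (n_perm + 1)``.

    Returns ``{"observed", "p", "n_pairs_used", "n_perm"}`` or
    ``{"applicable": False}`` when no close pair has complete data.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    df = records.dropna(subset=["d13C_permil", "d15N_permil"])
    labels = df["sample"].tolist()
    coords = df[["d13C_permil", "d15N_permil"]].to_numpy(dtype=float)
    coords = coords * np.asarray(weights, dtype=float)
    index = {s: i for i, s in enumerate(labels)}
    pairs = [
        (index[a], index[b])
        for a, b in close_pairs
        if a in index and b in index
    ]
    if not pairs:
        return {"applicable": False}
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])

    def mean_distance(c: np.ndarray) -> float:
        return float(np.linalg.norm(c[ii] - c[jj], axis=1).mean())

    observed = mean_distance(coords)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(coords))
        if mean_distance(coords[perm]) <= observed:
            hits += 1
    return {
        "applicable": True,
        "observed": observed,
        "p": (1 + hits) / (n_perm + 1),
        "n_pairs_used": len(pairs),
        "n_perm": n_perm,
    }
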