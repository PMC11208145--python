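"""Genetic sex assignment from relative X/Y coverage.

A male carries one X and one Y chromosome, so at equal sequencing effort
the per-site depth on X and Y targeted SNPs is about half the autosomal
depth; a female carries two X and no Y.  The classifier therefore works on
the *X rate* and *Y rate*: per-site coverage on X (resp. Y) targeted SNPs
divided by per-site autosomal coverage.

Decision windows (inclusive at both ends):

* male: 0.35 <= x_rate <= 0.55 and 0.4 <= y_rate <= 0.7
* female: x_rate >= 0.8 and y_rate <= 0.1
* anything else: indeterminate

The male window is the published confirmation window for capture data; the
female window follows standard practice (a small Y rate tolerance absorbs
spurious Y mapping).  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidParameterError, UndefinedRateError

MALE_X_WINDOW = (0.35, 0.55)
MALE_Y_WINDOW = (0.4, 0.7)
FEMALE_X_MIN = 0.8
FEMALE_Y_MAX = 0.1


@dataclass
class CoverageRates:
    """Per-sample X/Y coverage rates relative to autosomes, plus the call."""

    sample: str
    x_rate: float
    y_rate: float
    sex_call: str | None = None


def compute_rates(rows: pd.DataFrame) -> CoverageRates:
    """Coverage rates for one sample from its coverage-table rows.

    ``rows`` holds that sample's ``chromosome_class``/``sites_covered``/
    ``total_reads`` entries.  Each class's per-site depth is total reads
    divided by targeted sites; the X and Y rates are those depths divided by
    the autosomal depth.

    Raises
    ------
    UndefinedRateError
        If autosomal coverage is zero (the rates are then undefined).
    """
    by_class = {}
    for rec in rows.itertuples(index=False):
        cls = rec.chromosome_class
        if rec.sites_covered <= 0:
            raise InvalidParameterError(f"{cls}: sites_covered must be positive")
        by_class[cls] = rec.total_reads / rec.sites_covered
    for cls in ("autosome", "X", "Y"):
        if cls not in by_class:
            raise InvalidParameterError(f"missing coverage row for class {cls!r}")
    if by_class["autosome"] <= 0:
        raise UndefinedRateError("zero autosomal coverage; rates undefined")
    sample = str(rows["sample"].iloc[0])
    return CoverageRates(
        sample=sample,
        x_rate=by_class["X"] / by_class["autosome"],
        y_rate=by_class["Y"] / by_class["autosome"],
    )


def assign_sex(
    rates: CoverageRates,
    male_x: tuple[float, float] = MALE_X_WINDOW,
    male_y: tuple[float, float] = MALE_Y_WINDOW,
    female_x_min: float = FEMALE_X_MIN,
    female_y_max: float = FEMALE_Y_MAX,
) -> CoverageRates:
    """Fill in ``sex_call`` from the threshold windows (bounds inclusive)."""
    x, y = rates.x_rate, rates.y_rate
    if male_x[0] <= x <= male_x[1] and male_y[0] <= y <= male_y[1]:
        call = "male"
    elif x >= female_x_min and y <= female_y_max:
        call = "female"
    else:
        call = "indeterminate"
    rates.sex_call = call
    return rates


def sex_calls(coverage: pd.DataFrame, **windows) -> pd.DataFrame:
    """Compute rates and assign sex for every sample in a coverage table."""
    out = []
    for sample, rows in coverage.groupby("sample", sort=True):
        r = assign_sex(compute_rates(rows), **windows)
        out.append((sample, r.x_rate, r.y_rate, r.sex_call))
    return pd.DataFrame(out, columns=["sample", "x_rate", "y_rate", "sex_call"])
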