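"""Summary statistics for embryo staining count tables.

Rows are (genotype, assay, positive, total) counts of embryos scored
positive for a marker.  Percentages are reported as integers rounded
half away from zero, the convention consistent with published staining
tables (e.g. 1/40 → 2.5 → 3).  Wilson score intervals and Fisher exact
tests are provided as uncertainty/comparison plumbing on top of the raw
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError


def load_reference_counts() -> pd.DataFrame:
    """Bundled PGC staining counts (positive/total per genotype and assay:
    persistent Pol II Ser2 phosphorylation by H5, and H3K4me2
    reappearance, in late-stage embryos)."""
    from importlib.resources import files
    path = files("mesmark.data").joinpath("pgc_staining_counts.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class StainRow:
    genotype: str
    assay: str
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError("total must be > 0")
        if not 0 <= self.positive <= self.total:
            raise ValidationError("need 0 <= positive <= total")


def percent_positive(positive: int, total: int) -> tuple[int, float]:
    """Percentage positive, rounded half away from zero.

    Returns ``(rounded_percent, exact_percent)``.
    """
    if total <= 0:
        raise ValidationError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValidationError("need 0 <= positive <= total")
    exact = 100.0 * positive / total
    rounded = int(math.floor(exact + 0.5))  # counts are nonnegative
    return rounded, exact


def proportion_ci(positive: int, total: int,
                  level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the positive proportion."""
    if total <= 0:
        raise ValidationError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValidationError("need 0 <= positive <= total")
    lo, hi = proportion_confint(positive, total, alpha=1 - level,
                                method="wilson")
    # at the boundaries the Wilson limits are exactly 0 / 1; strip the
    # floating-point residue
    if positive == 0:
        lo = 0.0
    if positive == total:
        hi = 1.0
    return float(lo), float(hi)


def compare_genotypes(row_a: StainRow, row_b: StainRow) -> float:
    """Two-sided Fisher exact p-value for a difference between genotypes."""
    if row_a.assay != row_b.assay:
        raise ValidationError("rows being compared must share an assay")
    table = [[row_a.positive, row_a.total - row_a.positive],
             [row_b.positive, row_b.total - row_b.positive]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def summarize_table(table: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Percent positive and Wilson CI for every row of a count table.

    Expects columns ``genotype, assay, positive, total``.
    """
    required = ["genotype", "assay", "positive", "total"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"count table missing columns: {missing}")
    rows = []
    for rec in table.itertuples(index=False):
        pct, exact = percent_positive(int(rec.positive), int(rec.total))
        lo, hi = proportion_ci(int(rec.positive), int(rec.total), ci_level)
        rows.append((rec.genotype, rec.assay, int(rec.positive),
                     int(rec.total), pct, exact, lo, hi))
    return pd.DataFrame(rows, columns=["genotype", "assay", "positive",
                                       "total", "percent", "percent_exact",
                                       "ci_lo", "ci_hi"])
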