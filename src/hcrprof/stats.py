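"""Supporting statistics: phenotype scoring proportions, ΔΔCt qPCR fold
changes, and two-group fold-change tests.

These mirror the routine numeric computations that accompany an
embryo-scoring / qPCR study: percentages of affected embryos with Wilson
score intervals, Livak-style relative quantification against a reference
gene (ornithine decarboxylase, ODC, by default), and Welch's unpaired
two-tailed t-test on expression values such as TPMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ScoringRecord",
    "score_phenotypes",
    "ddct_fold_change",
    "fold_change_test",
]


@dataclass(frozen=True)
class ScoringRecord:
    """Counts behind one printed scoring percentage."""

    condition: str
    marker: str
    n_scored: int
    n_affected: int

    def __post_init__(self) -> None:
        if self.n_scored < 1:
            raise ValueError(f"n_scored: must be >= 1, got {self.n_scored}")
        if not 0 <= self.n_affected <= self.n_scored:
            raise ValueError(
                f"n_affected: must be in [0, n_scored={self.n_scored}], got {self.n_affected}"
            )


def score_phenotypes(records: list[ScoringRecord], conf_level: float = 0.95) -> pd.DataFrame:
    """Percent affected per (condition, marker) with a Wilson score interval.

    The percentage is exact rational arithmetic (100 * n_affected / n_scored)
    before any rounding; the Wilson interval is robust at the extreme
    proportions typical of scoring data and always lies within [0, 100].
    """
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    rows = []
    for rec in records:
        lo, hi = proportion_confint(
            rec.n_affected, rec.n_scored, alpha=1.0 - conf_level, method="wilson"
        )
        rows.append(
            {
                "condition": rec.condition,
                "marker": rec.marker,
                "n_scored": rec.n_scored,
                "n_affected": rec.n_affected,
                "percent_affected": 100.0 * rec.n_affected / rec.n_scored,
                # statsmodels can overshoot [0, 1] by one ulp at the boundaries
                "ci_low": float(np.clip(100.0 * lo, 0.0, 100.0)),
                "ci_high": float(np.clip(100.0 * hi, 0.0, 100.0)),
            }
        )
    return pd.DataFrame(rows)


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_gene: str = "ODC",
    control_label: str = "control",
    treated_label: str = "treated",
) -> pd.DataFrame:
    """Livak ΔΔCt relative quantification from a long-format Ct table.

    ``ct`` needs columns ``sample_group``, ``replicate``, ``gene``, ``ct``.
    Per replicate, ΔCt = Ct(gene) − Ct(reference_gene); ΔΔCt is the difference
    of the group means (treated − control); fold change = 2^(−ΔΔCt).  ΔΔCt is
    invariant to adding a constant to all Ct values of a replicate, since the
    reference subtraction removes it.
    """
    required = {"sample_group", "replicate", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")

    wide = ct.pivot_table(
        index=["sample_group", "replicate"], columns="gene", values="ct", aggfunc="mean"
    )
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from the Ct table")
    ref = wide[reference_gene]
    bad = ref[ref.isna()]
    if len(bad):
        group, rep = bad.index[0]
        raise ValueError(
            f"missing reference gene {reference_gene!r} Ct for group {group!r}, replicate {rep!r}"
        )

    rows = []
    targets = [g for g in wide.columns if g != reference_gene]
    for gene in targets:
        dct = wide[gene] - ref
        mean_control = float(dct.loc[control_label].mean())
        mean_treated = float(dct.loc[treated_label].mean())
        ddct = mean_treated - mean_control
        rows.append(
            {
                "gene": gene,
                "mean_dct_control": mean_control,
                "mean_dct_treated": mean_treated,
                "ddct": ddct,
                "fold_change": float(2.0 ** (-ddct)),
            }
        )
    return pd.DataFrame(rows)


def fold_change_test(
    groups: pd.DataFrame,
    gene_col: str = "gene",
    group_col: str = "group",
    value_col: str = "value",
    numerator: str | None = None,
    denominator: str | None = None,
) -> pd.DataFrame:
    """Fold change of group means plus Welch's unpaired two-tailed t-test, per gene.

    ``numerator``/``denominator`` name the two group labels; by default the
    first two labels in order of appearance.  When both groups have zero
    within-group variance and different means the p-value is reported as
    exactly 0 with ``zero_variance=True`` (rather than NaN); identical
    constant groups give t = 0, p = 1.
    """
    labels = list(dict.fromkeys(groups[group_col]))
    if numerator is None or denominator is None:
        if len(labels) != 2:
            raise ValueError(
                f"expected exactly 2 group labels, got {labels}; "
                "pass numerator/denominator explicitly"
            )
        numerator, denominator = labels

    rows = []
    for gene, sub in groups.groupby(gene_col, sort=False):
        a = sub.loc[sub[group_col] == numerator, value_col].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == denominator, value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"gene {gene!r}: each group needs >= 2 values")
        mb = float(b.mean())
        if mb == 0.0:
            raise ValueError(f"gene {gene!r}: denominator group mean is zero")
        fold = float(a.mean()) / mb

        zero_var = a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0
        if zero_var:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = float(np.inf if a.mean() > b.mean() else -np.inf)
                p = 0.0
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "gene": gene,
                "fold_change": fold,
                "t_statistic": t,
                "p_value": p,
                "zero_variance": zero_var,
                "test": "welch_two_tailed",
            }
        )
    return pd.DataFrame(rows)
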