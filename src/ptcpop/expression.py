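"""Expression breadth, quantile-normalized tissue specificity (tau), and
allele-imbalance testing.

The input is a gene x array matrix of linear-scale signal values with a
matching boolean present/absent call matrix; columns carry a two-level
(tissue, replicate) index. A tissue counts as expressing a gene only when
the gene is called present in *all* replicates of that tissue.

Normalization follows the quantile-profile recipe: log10-transform each
array, subtract the array mean, add back the grand mean over arrays; per
tissue, the replicate median is taken, and the present genes are split into
ten equal-density groups (1 = lowest ... 10 = highest), with absent genes
in group 0. The specificity index is computed on these discretized profiles:

    tau = sum_i (1 - x_i / x_max) / (N - 1)

over all N tissues (group-0 entries included); tau is undefined (NaN) for
genes with all-zero profiles.

The allele-imbalance test compares the expression of strains carrying the
derived allele with strains carrying the ancestral allele using the
two-sided Wilcoxon rank-sum test, with false discovery control by the
Storey-Tibshirani q-value procedure (fixed-lambda pi0 estimator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "expression_breadth",
    "tissue_present",
    "quantile_normalize_profiles",
    "compute_tau",
    "top_tissue",
    "summarize_expression",
    "tissue_specific_set",
    "storey_qvalues",
    "allele_imbalance_test",
    "allele_imbalance_scan",
]

NO_EXPRESSION = "no_expression"
TAU_CUTOFF = 0.85
N_QUANTILE_GROUPS = 10


def _check_matrix(values: pd.DataFrame) -> None:
    if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
        raise ValueError("expected columns indexed by (tissue, replicate)")


def tissue_present(present: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue present call: present in every replicate (genes x tissues)."""
    _check_matrix(present)
    return present.T.groupby(level=0).all().T


def expression_breadth(present: pd.DataFrame) -> pd.Series:
    """Number of tissues in which each gene is present across all replicates."""
    return tissue_present(present).sum(axis=1).rename("breadth")


def _normalize_arrays(values: pd.DataFrame, present: pd.DataFrame) -> pd.DataFrame:
    if ((values <= 0) & present).any().any():
        raise ValueError("non-positive signal value flagged present")
    logged = np.log10(values.where(values > 0))
    array_means = logged.mean(axis=0)
    grand_mean = array_means.mean()
    return logged.sub(array_means, axis=1) + grand_mean


def tissue_medians(values: pd.DataFrame, present: pd.DataFrame) -> pd.DataFrame:
    """Normalized per-tissue replicate-median expression (genes x tissues)."""
    _check_matrix(values)
    norm = _normalize_arrays(values, present)
    return norm.T.groupby(level=0).median().T


def quantile_normalize_profiles(
    values: pd.DataFrame, present: pd.DataFrame
) -> pd.DataFrame:
    """Discretize each tissue's expression into equal-density groups 0-10.

    Per tissue, genes present in all replicates are ranked by normalized
    replicate-median value (ties broken by gene label) and split into ten
    groups of as-equal-as-possible size; absent genes get group 0.
    """
    medians = tissue_medians(values, present)
    t_present = tissue_present(present)
    groups = pd.DataFrame(0, index=values.index, columns=medians.columns, dtype=int)
    for tissue in medians.columns:
        mask = t_present[tissue]
        sub = medians.loc[mask, tissue]
        n = len(sub)
        if n == 0:
            continue
        order = sub.reset_index()
        order.columns = ["gene", "value"]
        order = order.sort_values(["value", "gene"], kind="mergesort")
        ranks = np.arange(n)
        grp = ranks * N_QUANTILE_GROUPS // n + 1
        groups.loc[order["gene"].to_numpy(), tissue] = grp
    return groups


def compute_tau(profile: Sequence[float]) -> float:
    """Tissue-specificity index on a discretized profile; NaN if all zero."""
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least two tissues")
    x_max = x.max()
    if x_max == 0:
        return float("nan")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))


def top_tissue(
    medians_row: pd.Series, present_row: pd.Series
) -> str:
    """Highest-expressing tissue among those passing the present rule.

    Ties go to the lexicographically smallest tissue label; genes present
    nowhere return :data:`NO_EXPRESSION`.
    """
    candidates = medians_row[present_row.reindex(medians_row.index).fillna(False)]
    if candidates.empty:
        return NO_EXPRESSION
    best = candidates.max()
    return sorted(candidates[candidates == best].index)[0]


def summarize_expression(values: pd.DataFrame, present: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary: BREADTH, TAU, TOP_TISSUE."""
    medians = tissue_medians(values, present)
    t_present = tissue_present(present)
    profiles = quantile_normalize_profiles(values, present)
    breadth = expression_breadth(present)
    tau = profiles.apply(lambda row: compute_tau(row.to_numpy()), axis=1)
    top = pd.Series(
        [top_tissue(medians.loc[g], t_present.loc[g]) for g in values.index],
        index=values.index,
    )
    return pd.DataFrame({"BREADTH": breadth, "TAU": tau, "TOP_TISSUE": top})


def tissue_specific_set(
    summaries: pd.DataFrame, tau_cutoff: float = TAU_CUTOFF
) -> pd.Index:
    """Genes with defined tau strictly greater than the cutoff."""
    tau = summaries["TAU"]
    return summaries.index[tau.notna() & (tau > tau_cutoff)]


# ----------------------------------------------------------------------
# Storey-Tibshirani q-values
# ----------------------------------------------------------------------

def storey_qvalues(pvalues: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """q-values with the fixed-lambda pi0 estimator.

    pi0 = #{p > lambda} / ((1 - lambda) m), clipped to [1/m, 1]; q-values
    are the monotonized pi0-scaled BH quantities.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    pi0 = np.sum(p > lambda_) / ((1.0 - lambda_) * m)
    pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# ----------------------------------------------------------------------
# allele imbalance
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ImbalanceResult:
    statistic: float
    p: float
    direction: str  # lower_in_derived | lower_in_ancestral | none


def allele_imbalance_test(
    derived_values: Sequence[float], ancestral_values: Sequence[float]
) -> ImbalanceResult:
    """Two-sided rank-sum comparison of derived- vs ancestral-allele strains.

    Direction is read off the Mann-Whitney U statistic (number of
    derived > ancestral pairs, ties counted half): below its null mean the
    derived class is the lower one.
    """
    d = np.asarray(derived_values, dtype=float)
    a = np.asarray(ancestral_values, dtype=float)
    if d.size < 2 or a.size < 2:
        raise ValueError("need at least two strains per allele class")
    # exact null distribution where feasible (small, tie-free samples);
    # the tie-corrected normal approximation otherwise
    has_ties = np.unique(np.concatenate([d, a])).size < d.size + a.size
    method = "exact" if not has_ties and d.size * a.size <= 400 else "asymptotic"
    u, p = mannwhitneyu(d, a, alternative="two-sided", method=method)
    mid = d.size * a.size / 2.0
    if u < mid:
        direction = "lower_in_derived"
    elif u > mid:
        direction = "lower_in_ancestral"
    else:
        direction = "none"
    return ImbalanceResult(float(u), float(p), direction)


def allele_imbalance_scan(
    tests: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the imbalance test over many variants and attach q-values.

    ``tests`` maps a variant key to ``(derived_values, ancestral_values)``.
    Variants with fewer than two strains in either class are skipped and
    reported with NaN statistics. Returns columns STAT, P, Q, DIRECTION,
    SIGNIFICANT.
    """
    rows = {}
    for key, (d, a) in tests.items():
        if len(d) < 2 or len(a) < 2:
            rows[key] = (float("nan"), float("nan"), "skipped")
            continue
        res = allele_imbalance_test(d, a)
        rows[key] = (res.statistic, res.p, res.direction)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["STAT", "P", "DIRECTION"]
    )
    tested = df["P"].notna()
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = storey_qvalues(df.loc[tested, "P"].to_numpy())
    df["Q"] = q
    df["SIGNIFICANT"] = df["Q"] < q_threshold
    return df[["STAT", "P", "Q", "DIRECTION", "SIGNIFICANT"]]
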