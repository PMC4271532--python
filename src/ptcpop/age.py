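"""Gene age, origination mechanism, and duplicate-divergence analyses.

Genes are split into *young* (originated after the Sophophora/Drosophila
subgenus split, roughly the last 60 My; branch labels >= 1) and *old*
(branch <= 0), and young genes carry an origination mechanism: DNA-based
duplication, RNA-based duplication (retroposition), or de novo origination.
The cross-tabulations count genes by age class against PTC frequency
columns (PTC-free / low / moderate / high); for duplicates, a *strict* mode
restricts to genes whose parent copy is strictly older than the child.

Synonymous divergence between a parent-child duplicate pair (a proxy for
pair age) is computed with the Nei-Gojobori (1986) pathway-counting method:
per-codon synonymous site fractions averaged over the two sequences,
substitutions counted along all orderings of the within-codon differences
with equal weight, and a Jukes-Cantor multiple-hit correction
``d = -(3/4) ln(1 - (4/3) p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, linregress, spearmanr

from .seq import CODON_TABLE

__all__ = [
    "AgeRecord",
    "DuplicatePair",
    "load_table2",
    "table2_dataset",
    "age_frequency_crosstab",
    "mechanism_crosstab",
    "parent_child_comparison",
    "pairwise_ds",
    "ds_binned_distribution",
    "age_trend",
]

MECHANISMS = ("dna_duplication", "rna_duplication", "de_novo")
FREQ_COLUMNS = ("ptc_free", "low", "moderate", "high")


@dataclass(frozen=True)
class AgeRecord:
    gene_id: str
    branch: int  # >= 1 young, <= 0 old
    young: bool
    mechanism: str  # dna_duplication | rna_duplication | de_novo | none
    parent_gene: str | None = None
    strict_parent_child: bool = False

    def __post_init__(self) -> None:
        if self.young != (self.branch >= 1):
            raise ValueError(f"{self.gene_id}: young flag inconsistent with branch")


@dataclass(frozen=True)
class DuplicatePair:
    parent_id: str
    child_id: str
    s_value: float
    mechanism: str = "dna_duplication"


# ----------------------------------------------------------------------
# packaged printed-counts fixture
# ----------------------------------------------------------------------

def load_table2() -> pd.DataFrame:
    """Printed young/old x PTC-frequency counts shipped with the package."""
    with resources.files("ptcpop.data").joinpath("table2_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table2_dataset() -> tuple[list[AgeRecord], dict[str, str]]:
    """Expand the printed counts into per-gene age records and PTC groups.

    Young genes are partitioned by the raw per-mechanism counts (their
    column sums equal the young-gene row); within each mechanism cell the
    first *strict* genes are flagged as having a strictly older parent.
    Returns ``(age_records, ptc_group_by_gene)`` where genes without PTCs
    are absent from the mapping.
    """
    tab = load_table2().set_index(["category", "mode"])
    records: list[AgeRecord] = []
    groups: dict[str, str] = {}

    def emit(prefix: str, branch: int, mech: str, col: str, n_total: int, n_strict: int):
        for i in range(n_total):
            gid = f"{prefix}_{col}_{i:05d}"
            records.append(
                AgeRecord(
                    gene_id=gid,
                    branch=branch,
                    young=branch >= 1,
                    mechanism=mech,
                    parent_gene=None,
                    strict_parent_child=i < n_strict and mech != "de_novo",
                )
            )
            if col != "ptc_free":
                groups[gid] = col

    for col in FREQ_COLUMNS:
        emit("old", 0, "none", col, int(tab.loc[("old", "all"), col]), 0)
        for mech in MECHANISMS:
            raw = int(tab.loc[(mech, "raw"), col])
            strict = int(tab.loc[(mech, "strict"), col])
            emit(mech, 1, mech, col, raw, strict)
    return records, groups


# ----------------------------------------------------------------------
# cross-tabulations
# ----------------------------------------------------------------------

def _gene_column(record: AgeRecord, ptc_groups: Mapping[str, str]) -> str:
    return ptc_groups.get(record.gene_id, "ptc_free")


def age_frequency_crosstab(
    ages: Sequence[AgeRecord], ptc_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Old/young gene counts per PTC frequency column.

    Rows ``old`` and ``young`` hold counts; ``percent_young`` is the
    young / (young + old) share per column rounded to integer percent.
    """
    counts = pd.DataFrame(0, index=["old", "young"], columns=list(FREQ_COLUMNS))
    for rec in ages:
        row = "young" if rec.young else "old"
        counts.loc[row, _gene_column(rec, ptc_groups)] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.round(100.0 * counts.loc["young"] / totals).fillna(0.0)
    out = counts.astype(float)
    out.loc["percent_young"] = pct
    return out


def mechanism_crosstab(
    ages: Sequence[AgeRecord],
    ptc_groups: Mapping[str, str],
    strict: bool = True,
) -> pd.DataFrame:
    """Young-gene counts per origination mechanism and frequency column.

    In strict mode, duplicates are restricted to genes with a strictly
    older parent; de novo genes have no parent and are always included.
    Adds derived columns: ``total``, ``n_ptc``, ``ptc_fraction``,
    ``n_moderate_high``, ``moderate_high_fraction``.
    """
    counts = pd.DataFrame(0, index=list(MECHANISMS), columns=list(FREQ_COLUMNS))
    for rec in ages:
        if not rec.young or rec.mechanism not in MECHANISMS:
            continue
        if strict and rec.mechanism != "de_novo" and not rec.strict_parent_child:
            continue
        counts.loc[rec.mechanism, _gene_column(rec, ptc_groups)] += 1
    out = counts.copy()
    out["total"] = counts.sum(axis=1)
    out["n_ptc"] = counts[["low", "moderate", "high"]].sum(axis=1)
    out["ptc_fraction"] = out["n_ptc"] / out["total"]
    out["n_moderate_high"] = counts[["moderate", "high"]].sum(axis=1)
    out["moderate_high_fraction"] = out["n_moderate_high"] / out["total"]
    return out


def parent_child_comparison(
    pairs: Sequence[DuplicatePair], ptc_genes: Iterable[str]
) -> tuple[int, int, float]:
    """PTC burden in child vs parent copies over duplicate pairs.

    Returns ``(n_child_ptc, n_parent_ptc, fet_p)`` with a two-sided FET on
    the two proportions out of the same pair count.
    """
    ptc = set(ptc_genes)
    n = len(pairs)
    n_child = sum(1 for pr in pairs if pr.child_id in ptc)
    n_parent = sum(1 for pr in pairs if pr.parent_id in ptc)
    if n == 0:
        return 0, 0, 1.0
    _, p = fisher_exact([[n_child, n - n_child], [n_parent, n - n_parent]])
    return n_child, n_parent, float(p)


# ----------------------------------------------------------------------
# NG86 synonymous divergence
# ----------------------------------------------------------------------

_BASES = "ACGT"


def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon (changes to stop = nonsynonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for b in _BASES
            if b != codon[pos]
            and CODON_TABLE[codon[:pos] + b + codon[pos + 1 :]] == aa
        )
        s += syn / 3.0
    return s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) substitution counts."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    paths = list(permutations(diffs))
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd_tot += 1.0
            else:
                nd_tot += 1.0
            cur = nxt
    k = len(paths)
    return sd_tot / k, nd_tot / k


def pairwise_ds(cds1: str, cds2: str) -> float:
    """NG86 synonymous substitutions per synonymous site with JC correction.

    The two CDS must be equal-length and frame-aligned. Trailing stop
    codons and codon pairs containing a stop or an ambiguous base are
    skipped. Returns NaN when the synonymous difference proportion reaches
    the Jukes-Cantor saturation bound (p_s >= 0.75).
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned CDS pair must have equal length")
    if len(cds1) % 3:
        raise ValueError("CDS length not a multiple of three")
    cds1, cds2 = cds1.upper(), cds2.upper()
    s_sites = 0.0
    sd = 0.0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if set(c1 + c2) - set(_BASES):
            continue
        if CODON_TABLE[c1] == "*" or CODON_TABLE[c2] == "*":
            continue
        s_sites += (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        sd += _path_counts(c1, c2)[0]
    if s_sites == 0:
        return float("nan")
    p_s = sd / s_sites
    if p_s >= 0.75:
        return float("nan")
    return float(-0.75 * np.log(1.0 - 4.0 * p_s / 3.0))


def ds_binned_distribution(
    pairs: Sequence[DuplicatePair], bin_width: float = 0.1
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalized per-mechanism histogram of duplicate-pair divergence.

    Returns mechanism -> (bin_edges, fractions); pairs with undefined
    (NaN) divergence are dropped. Bin edges are shared across mechanisms.
    """
    s_all = [pr.s_value for pr in pairs if np.isfinite(pr.s_value)]
    if not s_all:
        return {}
    n_bins = max(1, int(np.ceil(max(s_all) / bin_width)) or 1)
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] <= max(s_all):
        edges = np.append(edges, edges[-1] + bin_width)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for mech in sorted({pr.mechanism for pr in pairs}):
        vals = [
            pr.s_value
            for pr in pairs
            if pr.mechanism == mech and np.isfinite(pr.s_value)
        ]
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        frac = counts / total if total else counts.astype(float)
        out[mech] = (edges, frac)
    return out


# ----------------------------------------------------------------------
# age trend
# ----------------------------------------------------------------------

def age_trend(
    ages: Sequence[AgeRecord],
    ptc_groups: Mapping[str, str],
    branch_midpoints: Mapping[int, float],
    groups: Sequence[str] = ("low", "moderate", "high"),
    exclude_branches: Sequence[int] = (),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-branch PTC-encoding gene fraction with rank and linear fits.

    ``branch_midpoints`` maps branch label to its midpoint age in million
    years (negative = past). ``groups`` selects which frequency columns
    count as PTC-encoding (e.g. only moderate+high). Excluded branches are
    kept in the table but flagged and left out of the fits. Constant
    fractions yield NaN correlation without error.
    """
    wanted = set(groups)
    per_branch: dict[int, list[int]] = {}
    for rec in ages:
        if rec.branch not in branch_midpoints:
            continue
        tally = per_branch.setdefault(rec.branch, [0, 0])
        tally[0] += 1
        if ptc_groups.get(rec.gene_id) in wanted:
            tally[1] += 1
    rows = []
    for branch in sorted(per_branch):
        n, k = per_branch[branch]
        rows.append(
            {
                "branch": branch,
                "midpoint_mya": branch_midpoints[branch],
                "n_genes": n,
                "n_ptc": k,
                "fraction": k / n if n else np.nan,
                "excluded": branch in set(exclude_branches),
            }
        )
    table = pd.DataFrame(rows)
    fit = table[~table["excluded"]]
    stats: dict[str, float] = {
        "rho": np.nan,
        "rho_p": np.nan,
        "slope": np.nan,
        "intercept": np.nan,
    }
    if len(fit) >= 3 and fit["fraction"].nunique() > 1:
        rho, p = spearmanr(fit["midpoint_mya"], fit["fraction"])
        reg = linregress(fit["midpoint_mya"], fit["fraction"])
        stats.update(
            rho=float(rho), rho_p=float(p),
            slope=float(reg.slope), intercept=float(reg.intercept),
        )
    return table, stats
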