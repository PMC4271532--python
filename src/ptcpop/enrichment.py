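"""Enrichment statistics: multinomial confidence ribbons, Fisher exact
tests, top-tissue and chromosome distribution reports.

The ribbon treats the per-tissue counts of focal genes as a multinomial
draw with genome-wide category proportions; a simultaneous band at a 5%
family-wide type-I error rate is built from Monte-Carlo draws with
Sidak-adjusted per-category quantile levels.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .expression import NO_EXPRESSION

__all__ = [
    "multinomial_ribbon",
    "fisher_enrichment",
    "genes_by_max_daf_group",
    "top_tissue_group_report",
    "chromosome_distribution_test",
    "plot_top_tissue_scatter",
]

FREQ_GROUPS = ("low", "moderate", "high")


def multinomial_ribbon(
    genome_counts: Mapping[str, int] | pd.Series,
    n_group: int,
    family_alpha: float = 0.05,
    n_sim: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected counts and simultaneous confidence band per category.

    ``genome_counts`` gives the genome-wide gene count per category;
    expected counts are ``n_group * p_k``. The band is built by drawing
    ``n_sim`` multinomials and taking per-category quantiles at a common
    level, starting from the Sidak adjustment
    ``1 - (1 - family_alpha)^(1/K)`` and widened by bisection to the
    loosest level whose simulated family-wide coverage still reaches
    ``1 - family_alpha`` (count discreteness makes the plain Sidak band
    over-cover).
    """
    counts = pd.Series(genome_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("genome category counts sum to zero")
    if n_group < 1:
        raise ValueError("n_group must be >= 1")
    p = (counts / total).to_numpy()
    k = len(counts)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_group, p, size=n_sim)

    def band(alpha_c: float) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(draws, alpha_c / 2.0, axis=0)
        hi = np.quantile(draws, 1.0 - alpha_c / 2.0, axis=0)
        return lo, hi

    def coverage(b: tuple[np.ndarray, np.ndarray]) -> float:
        lo, hi = b
        return float(((draws >= lo) & (draws <= hi)).all(axis=1).mean())

    # Sidak level as starting point; counts are discrete, so the Sidak band
    # over-covers - widen alpha_c by bisection to the largest level still
    # holding family coverage >= 1 - family_alpha
    target = 1.0 - family_alpha
    a_lo = 1.0 - (1.0 - family_alpha) ** (1.0 / k)
    a_hi = min(1.0, 2.0 * family_alpha)
    if coverage(band(a_hi)) >= target:
        a_lo = a_hi
    else:
        for _ in range(30):
            mid = (a_lo + a_hi) / 2.0
            if coverage(band(mid)) >= target:
                a_lo = mid
            else:
                a_hi = mid
    lower, upper = band(a_lo)
    return pd.DataFrame(
        {"expected": n_group * p, "lower": lower, "upper": upper},
        index=counts.index,
    )


def fisher_enrichment(
    a_in: int, a_total: int, b_in: int, b_total: int, sided: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on [[a_in, a_out], [b_in, b_out]].

    ``sided`` is one of ``two-sided``, ``greater`` (group A enriched),
    ``less``. Returns ``(odds_ratio, p)``.
    """
    if not (0 <= a_in <= a_total and 0 <= b_in <= b_total):
        raise ValueError("inconsistent contingency counts")
    table = [[a_in, a_total - a_in], [b_in, b_total - b_in]]
    odds, p = fisher_exact(table, alternative=sided)
    return float(odds), float(p)


def genes_by_max_daf_group(
    variant_groups: Iterable[tuple[str, str, float]]
) -> dict[str, str]:
    """Deduplicate multi-PTC genes: each gene keeps its highest-DAF group.

    ``variant_groups`` yields ``(gene_id, freq_group, daf)`` triples.
    """
    best: dict[str, tuple[float, str]] = {}
    for gene_id, group, daf in variant_groups:
        if gene_id not in best or daf > best[gene_id][0]:
            best[gene_id] = (daf, group)
    return {g: grp for g, (_, grp) in best.items()}


def top_tissue_group_report(
    top_tissue_by_gene: Mapping[str, str],
    group_by_gene: Mapping[str, str],
    genome_top_tissue: Mapping[str, str],
    sex_tissues: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-frequency-group top-tissue composition with genome FETs.

    For each frequency group and each category (every tissue observed plus
    :data:`~ptcpop.expression.NO_EXPRESSION` and an aggregate
    ``sex_related`` row), reports the gene count, the proportion of the
    group, the proportion among expressed genes (no-expression genes
    excluded from the denominator), and a two-sided FET of the group count
    against the genome-wide background.
    """
    sex = set(sex_tissues)
    genome = pd.Series(genome_top_tissue)
    genome_n = len(genome)
    categories = sorted(set(genome.unique()) | set(top_tissue_by_gene.values()))
    genome_counts = genome.value_counts()
    genome_expressed = int((genome != NO_EXPRESSION).sum())
    genome_sex = int(genome.isin(sex).sum())

    rows = []
    for group in FREQ_GROUPS:
        members = [g for g, grp in group_by_gene.items() if grp == group]
        n = len(members)
        tops = pd.Series({g: top_tissue_by_gene.get(g, NO_EXPRESSION) for g in members})
        n_expressed = int((tops != NO_EXPRESSION).sum()) if n else 0
        for cat in categories:
            k = int((tops == cat).sum()) if n else 0
            gk = int(genome_counts.get(cat, 0))
            p = np.nan
            if n:
                _, p = fisher_enrichment(k, n, gk, genome_n)
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "n": k,
                    "group_total": n,
                    "proportion": k / n if n else np.nan,
                    "proportion_expressed": (
                        k / n_expressed if n_expressed and cat != NO_EXPRESSION else np.nan
                    ),
                    "genome_proportion": gk / genome_n,
                    "fet_p": p,
                }
            )
        if sex:
            k = int(tops.isin(sex).sum()) if n else 0
            p = np.nan
            if n_expressed:
                _, p = fisher_enrichment(k, n_expressed, genome_sex, genome_expressed)
            rows.append(
                {
                    "group": group,
                    "category": "sex_related",
                    "n": k,
                    "group_total": n,
                    "proportion": k / n if n else np.nan,
                    "proportion_expressed": k / n_expressed if n_expressed else np.nan,
                    "genome_proportion": genome_sex / genome_expressed
                    if genome_expressed
                    else np.nan,
                    "fet_p": p,
                }
            )
    return pd.DataFrame(rows)


def plot_top_tissue_scatter(
    band: pd.DataFrame,
    observed: Mapping[str, int],
    path: str,
    label_outliers: bool = True,
) -> None:
    """Expected-vs-observed scatter with the simultaneous confidence ribbon.

    ``band`` is the output of :func:`multinomial_ribbon`; ``observed`` maps
    category to the focal-group gene count. Written as SVG or PNG depending
    on the file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = band["expected"].sort_values().index
    exp = band.loc[order, "expected"]
    obs = pd.Series(observed).reindex(order).fillna(0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(exp, band.loc[order, "lower"], band.loc[order, "upper"],
                    color="0.85", label="95% family-wide band")
    ax.plot(exp, exp, color="0.4", lw=1, ls="--")
    ax.scatter(exp, obs, s=18, color="tab:blue", zorder=3)
    if label_outliers:
        outside = (obs < band.loc[order, "lower"]) | (obs > band.loc[order, "upper"])
        for cat in order[outside]:
            ax.annotate(cat, (exp[cat], obs[cat]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("expected genes (genome-wide proportions)")
    ax.set_ylabel("observed genes in focal group")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def chromosome_distribution_test(
    genes_by_group: Mapping[str, Iterable[str]],
    is_x: Mapping[str, bool],
) -> pd.DataFrame:
    """Per frequency group, FET of X-linked fraction against the genome.

    ``is_x`` flags every gene in the genome background. Single-gene and
    background-matching groups are reported, never suppressed.
    """
    genome_x = sum(1 for v in is_x.values() if v)
    genome_total = len(is_x)
    rows = []
    for group, genes in genes_by_group.items():
        genes = list(genes)
        n_x = sum(1 for g in genes if is_x[g])
        odds, p = fisher_enrichment(n_x, len(genes), genome_x, genome_total)
        rows.append(
            {
                "group": group,
                "n_x": n_x,
                "n_total": len(genes),
                "x_fraction": n_x / len(genes) if genes else np.nan,
                "genome_x_fraction": genome_x / genome_total,
                "odds_ratio": odds,
                "fet_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("group")
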