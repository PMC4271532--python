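"""FPR-stratified resampling robustness check.

Sanger validation of called PTCs gives each frequency group an estimated
false positive rate (low 20%, moderate 13%, high 0%). To test whether
group-dependent error rates confound downstream comparisons, pseudo
datasets are generated by randomly removing variants at the group-specific
FPR, and every headline summary is recomputed across replicates.

Removal is an independent Bernoulli draw per variant (keep probability
1 - FPR); a fixed-count mode that removes exactly ``round(FPR * n)``
variants per group is available behind a flag. Replicates are fully
determined by ``(seed, replicate_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

__all__ = ["ResamplingConfig", "make_pseudo_dataset", "resampled_summary", "ordering_fraction"]

T = TypeVar("T")

DEFAULT_FPR = {"low": 0.20, "moderate": 0.13, "high": 0.0}


@dataclass(frozen=True)
class ResamplingConfig:
    fpr_by_group: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FPR))
    n_replicates: int = 100
    seed: int = 0
    fixed_count: bool = False

    def __post_init__(self) -> None:
        for group, rate in self.fpr_by_group.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"FPR for {group!r} outside [0, 1]: {rate}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def make_pseudo_dataset(
    variants: Sequence[T],
    config: ResamplingConfig,
    replicate_index: int,
    group_of: Callable[[T], str],
) -> list[T]:
    """One pseudo dataset: variants removed at their group's FPR.

    ``group_of`` extracts the frequency-group label of a variant; variants
    whose group has no configured FPR are always kept.
    """
    rng = np.random.default_rng([config.seed, replicate_index])
    if not config.fixed_count:
        keep_p = np.array(
            [1.0 - config.fpr_by_group.get(group_of(v), 0.0) for v in variants]
        )
        keep = rng.random(len(keep_p)) < keep_p
        return [v for v, k in zip(variants, keep) if k]
    keep_mask = np.ones(len(variants), dtype=bool)
    groups = np.array([group_of(v) for v in variants])
    for group, rate in config.fpr_by_group.items():
        idx = np.flatnonzero(groups == group)
        n_remove = int(round(rate * idx.size))
        if n_remove:
            drop = rng.choice(idx, size=n_remove, replace=False)
            keep_mask[drop] = False
    return [v for v, k in zip(variants, keep_mask) if k]


def resampled_summary(
    variants: Sequence[T],
    config: ResamplingConfig,
    summary_fn: Callable[[list[T]], Mapping[str, float]],
    group_of: Callable[[T], str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a summary to every pseudo dataset and report stability.

    ``summary_fn`` maps a variant subset to named statistics. Returns
    ``(per_replicate, stability)``: one summary row per replicate, and per
    statistic the median and 2.5-97.5 percentile band (degenerate when a
    single replicate is drawn).
    """
    rows = []
    for r in range(config.n_replicates):
        subset = make_pseudo_dataset(variants, config, r, group_of)
        rows.append(dict(summary_fn(subset)))
    per_replicate = pd.DataFrame(rows)
    per_replicate.index.name = "replicate"
    stability = pd.DataFrame(
        {
            "median": per_replicate.median(),
            "p2.5": per_replicate.quantile(0.025),
            "p97.5": per_replicate.quantile(0.975),
        }
    )
    return per_replicate, stability


def ordering_fraction(per_replicate: pd.DataFrame, columns: Sequence[str]) -> float:
    """Fraction of replicates in which the named columns strictly increase."""
    vals = per_replicate[list(columns)].to_numpy()
    ok = np.all(np.diff(vals, axis=1) > 0, axis=1)
    return float(ok.mean())
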