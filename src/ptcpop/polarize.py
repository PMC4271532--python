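"""Ancestral-state inference, derived allele frequencies, frequency groups.

A polymorphism is polarized conservatively using two outgroup species: the
alternate allele is called *derived* if and only if the reference base and
both outgroup bases are identical. Sites where the outgroups instead match
the alternate allele, disagree with each other, or are missing remain
unpolarized and are dropped from frequency analyses.

Derived allele frequency (DAF) is the sample frequency over informative
(unambiguous A/C/G/T) strain alleles. Variants are binned into three
groups: low (DAF <= 1.5%), moderate (1.5% < DAF <= 10%), high (DAF > 10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .variants import ClassifiedSnp, SitePanel

__all__ = [
    "PolarizedVariant",
    "infer_ancestral",
    "compute_daf",
    "assign_frequency_group",
    "daf_spectrum",
    "compare_spectra",
    "daf_matched_sample",
]

LOW_MAX = 0.015
MODERATE_MAX = 0.10

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class PolarizedVariant:
    snp: ClassifiedSnp
    ancestral: str
    derived: str
    n_derived: int
    n_informative: int
    daf: float
    freq_group: str  # low | moderate | high

    @property
    def gene_id(self) -> str:
        return self.snp.gene_id


def infer_ancestral(
    ref_base: str, alt_base: str, outgroup1: str | None, outgroup2: str | None
) -> str | None:
    """Return the derived allele, or ``None`` when the site is unpolarizable.

    The rule is anchored on the reference base: ``alt`` is derived iff
    ``ref == outgroup1 == outgroup2``. Sites where both outgroups carry the
    alternate allele are deliberately left unpolarized (conservative, since
    the rule demands the reference strain share the outgroup base).
    """
    if outgroup1 is None or outgroup2 is None:
        return None
    if outgroup1 not in _VALID or outgroup2 not in _VALID:
        return None
    if ref_base == outgroup1 == outgroup2:
        return alt_base
    return None


def compute_daf(site: SitePanel, derived: str) -> tuple[int, int, float]:
    """Count the derived allele over unambiguous strain bases only."""
    informative = site.informative
    n_informative = len(informative)
    n_derived = sum(1 for a in informative if a == derived)
    daf = n_derived / n_informative if n_informative else float("nan")
    return n_derived, n_informative, daf


def assign_frequency_group(daf: float) -> str:
    """Bin a DAF: low (<=1.5%), moderate (1.5-10%], high (>10%)."""
    if not 0.0 <= daf <= 1.0:
        raise ValueError(f"DAF {daf} outside [0, 1]")
    if daf <= LOW_MAX:
        return "low"
    if daf <= MODERATE_MAX:
        return "moderate"
    return "high"


def polarize_variant(
    snp: ClassifiedSnp, outgroup1: str | None, outgroup2: str | None
) -> PolarizedVariant | None:
    """Full polarization of a classified SNP; ``None`` if unpolarizable."""
    derived = infer_ancestral(snp.ref, snp.alt, outgroup1, outgroup2)
    if derived is None:
        return None
    ancestral = snp.ref if derived == snp.alt else snp.alt
    n_der, n_inf, daf = compute_daf(snp.site, derived)
    return PolarizedVariant(
        snp=snp,
        ancestral=ancestral,
        derived=derived,
        n_derived=n_der,
        n_informative=n_inf,
        daf=daf,
        freq_group=assign_frequency_group(daf),
    )


# ----------------------------------------------------------------------
# spectra
# ----------------------------------------------------------------------

def daf_spectrum(
    variants: Sequence[PolarizedVariant], bins: Sequence[float]
) -> dict[str, np.ndarray]:
    """Normalized DAF histogram per functional class.

    ``bins`` are edges as for :func:`numpy.histogram`. Returns a mapping
    from site class to the normalized per-bin fractions; empty input gives
    an empty mapping.
    """
    out: dict[str, np.ndarray] = {}
    by_class: dict[str, list[float]] = {}
    for v in variants:
        by_class.setdefault(v.snp.site_class, []).append(v.daf)
    for cls, dafs in by_class.items():
        counts, _ = np.histogram(dafs, bins=np.asarray(bins, dtype=float))
        total = counts.sum()
        out[cls] = counts / total if total else counts.astype(float)
    return out


def compare_spectra(
    variants_a: Sequence[PolarizedVariant],
    variants_b: Sequence[PolarizedVariant],
    alternative: str = "less",
) -> tuple[float, float]:
    """Rank test on DAFs of class A vs class B (default: A skewed lower)."""
    a = [v.daf for v in variants_a]
    b = [v.daf for v in variants_b]
    stat, p = mannwhitneyu(a, b, alternative=alternative)
    return float(stat), float(p)


# ----------------------------------------------------------------------
# frequency-matched control sampling
# ----------------------------------------------------------------------

def daf_matched_sample(
    pool: Sequence[PolarizedVariant],
    template: Sequence[PolarizedVariant],
    n: int,
    seed: int,
) -> list[PolarizedVariant]:
    """Draw ``n`` control variants whose DAF multiset matches the template's.

    The template's DAFs are cycled ``n / len(template)`` times; each required
    DAF is matched to the unused pool variant with the nearest DAF (exact
    match when available), without replacement. Ties are broken by a seeded
    random ordering of the pool, so the draw is reproducible.
    """
    if n > len(pool):
        raise ValueError(f"cannot draw {n} variants from a pool of {len(pool)}")
    if not template:
        raise ValueError("empty template")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    pool_daf = np.array([pool[i].daf for i in order])
    used = np.zeros(len(pool), dtype=bool)
    targets = [template[i % len(template)].daf for i in range(n)]
    chosen: list[PolarizedVariant] = []
    for t in targets:
        dist = np.abs(pool_daf - t)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        used[j] = True
        chosen.append(pool[int(order[j])])
    return chosen
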