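"""SNP extraction and functional classification.

Per-site strain genotypes are parsed out of chromosome-length strain
consensus sequences ("pseudochromosomes") at reference coordinates.
Each biallelic SNP inside a gene is classified, isoform by isoform, as
synonymous / missense / nonsense by substituting the alternate base into
the reference codon (strand-aware) and comparing translations. A nonsense
change is *constitutive* when it creates a premature stop in every
annotated isoform; a putative PTC is accepted only when it is constitutive
and removes at least 5% of the coding region in each isoform.

Truncation is measured in codons: with L total codons in an isoform
(including the annotated stop) and a premature stop at 1-based codon i,
``truncation_fraction = (L - i) / (L - 1)`` - the fraction of the coding
region 3' of the new stop, the new stop codon itself excluded.

Site filters mirror the population-panel rules: biallelic only, no strain
heterozygous at the site (IUPAC ambiguity code), and at least 60 informative
(unambiguous A/C/G/T) bases across strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneModel, Isoform
from .seq import CODON_TABLE, HET_CODES, complement

__all__ = [
    "SitePanel",
    "IsoformEffect",
    "ClassifiedSnp",
    "extract_site_panel",
    "site_filters",
    "classify_coding_snp",
    "call_constitutive_ptc",
    "call_splice_disruption",
    "call_start_loss",
]

MIN_INFORMATIVE = 60
MIN_TRUNCATION = 0.05

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SitePanel:
    """Strain alleles observed at one reference position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    strain_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ref_base not in _VALID_BASES:
            raise ValueError(f"ref base {self.ref_base!r} is ambiguous")

    @property
    def informative(self) -> list[str]:
        return [a for a in self.strain_alleles if a in _VALID_BASES]

    def allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.informative:
            counts[a] = counts.get(a, 0) + 1
        return counts


@dataclass(frozen=True)
class IsoformEffect:
    transcript_id: str
    in_cds: bool
    effect: str  # nonsense | missense | synonymous | ref_stop | other
    truncation_fraction: float  # NaN unless nonsense

    @property
    def disrupts(self) -> bool:
        return self.effect == "nonsense"


@dataclass(frozen=True)
class ClassifiedSnp:
    site: SitePanel
    gene_id: str
    ref: str
    alt: str
    site_class: str  # nonsense | missense | synonymous | other
    per_isoform: tuple[IsoformEffect, ...]
    constitutive: bool

    @property
    def min_truncation(self) -> float:
        """Smallest truncation over isoforms; NaN unless all isoforms disrupt."""
        if not self.constitutive:
            return float("nan")
        return min(e.truncation_fraction for e in self.per_isoform)


# ----------------------------------------------------------------------
# site extraction and filters
# ----------------------------------------------------------------------

def extract_site_panel(
    panel: Mapping[str, np.ndarray],
    chrom: str,
    pos: int,
    ref_base: str,
) -> SitePanel:
    """Pull one column out of the strain x position allele matrix.

    ``panel`` maps chromosome name to a ``(n_strains, length)`` byte matrix
    (dtype ``S1``) of per-strain pseudochromosomes. No filtering is applied;
    N and heterozygote codes are retained as-is.
    """
    mat = panel[chrom]
    if not 1 <= pos <= mat.shape[1]:
        raise ValueError(f"position {pos} outside {chrom} (length {mat.shape[1]})")
    col = mat[:, pos - 1]
    alleles = tuple(b.decode() for b in col)
    return SitePanel(chrom=chrom, pos=pos, ref_base=ref_base, strain_alleles=alleles)


def site_filters(site: SitePanel, min_informative: int = MIN_INFORMATIVE) -> tuple[bool, str]:
    """Population-level filters; returns ``(passed, reason)``.

    Fail reasons, checked in order: ``heterozygous_line`` (any strain carries
    an IUPAC two-base code), ``not_biallelic`` (observed unambiguous alleles
    != 2), ``informative_lt_60`` (fewer than ``min_informative`` A/C/G/T
    symbols).
    """
    if any(a in HET_CODES for a in site.strain_alleles):
        return False, "heterozygous_line"
    counts = site.allele_counts()
    if len(counts) != 2:
        return False, "not_biallelic"
    if sum(counts.values()) < min_informative:
        return False, "informative_lt_60"
    return True, ""


# ----------------------------------------------------------------------
# coding classification
# ----------------------------------------------------------------------

def _isoform_effect(
    gene: GeneModel,
    isoform: Isoform,
    reference: Mapping[str, str],
    pos: int,
    alt: str,
) -> IsoformEffect:
    positions = gene.coding_positions(isoform)
    hits = np.flatnonzero(positions == pos)
    if hits.size == 0:
        return IsoformEffect(isoform.transcript_id, False, "other", float("nan"))
    idx = int(hits[0])
    cds = gene.cds_sequence(isoform, reference)
    codon_i = idx // 3
    within = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if CODON_TABLE[codon] == "*":
        # reference codon already a stop (the annotated stop): excluded from
        # PTC calling by definition
        return IsoformEffect(isoform.transcript_id, True, "ref_stop", float("nan"))
    alt_t = alt if gene.strand == "+" else complement(alt)
    mutant = codon[:within] + alt_t + codon[within + 1 :]
    aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutant]
    n_codons = len(cds) // 3
    if aa_alt == "*":
        trunc = (n_codons - (codon_i + 1)) / (n_codons - 1)
        return IsoformEffect(isoform.transcript_id, True, "nonsense", trunc)
    effect = "synonymous" if aa_alt == aa_ref else "missense"
    return IsoformEffect(isoform.transcript_id, True, effect, float("nan"))


def classify_coding_snp(
    site: SitePanel,
    gene: GeneModel,
    reference: Mapping[str, str],
    alt: str | None = None,
) -> ClassifiedSnp:
    """Classify a biallelic SNP against every isoform of ``gene``.

    The alternate allele defaults to the single non-reference base observed
    in the panel. The gene-level class is the most severe isoform effect
    (nonsense > missense > synonymous > other); ``constitutive`` is true iff
    the change creates a premature stop in *all* isoforms.
    """
    if alt is None:
        non_ref = {a for a in site.informative if a != site.ref_base}
        if len(non_ref) != 1:
            raise ValueError(
                f"{site.chrom}:{site.pos}: cannot infer a single alt allele "
                f"from {sorted(non_ref)}"
            )
        (alt,) = non_ref
    effects = tuple(
        _isoform_effect(gene, iso, reference, site.pos, alt) for iso in gene.isoforms
    )
    classes = [e.effect for e in effects]
    for cls in ("nonsense", "missense", "synonymous"):
        if cls in classes:
            site_class = cls
            break
    else:
        site_class = "other"
    constitutive = all(e.disrupts for e in effects)
    return ClassifiedSnp(
        site=site,
        gene_id=gene.gene_id,
        ref=site.ref_base,
        alt=alt,
        site_class=site_class,
        per_isoform=effects,
        constitutive=constitutive,
    )


def call_constitutive_ptc(
    snp: ClassifiedSnp, min_truncation: float = MIN_TRUNCATION
) -> tuple[bool, str]:
    """Accept a putative PTC; returns ``(accepted, reason)``.

    Accept iff the SNP is nonsense, constitutive, and removes at least
    ``min_truncation`` of the coding region in *each* isoform (inclusive
    boundary).
    """
    if snp.site_class != "nonsense":
        return False, "not_nonsense"
    if not snp.constitutive:
        return False, "not_constitutive"
    if snp.min_truncation < min_truncation:
        return False, "truncation_lt_5pct"
    return True, ""


# ----------------------------------------------------------------------
# splice and start-codon disruption
# ----------------------------------------------------------------------

def call_splice_disruption(
    site: SitePanel, gene: GeneModel, reference: Mapping[str, str]
) -> bool:
    """Flag substitutions at the terminal 2 bp of any intron of any isoform.

    Intron boundaries are compared at base-pair level; the 2 bp window at
    each intron end covers the canonical GT donor and AG acceptor
    dinucleotides (in transcription orientation).
    """
    pos = site.pos
    for iso in gene.isoforms:
        for lo, hi in gene.introns(iso):
            if hi < lo:  # degenerate (abutting segments)
                continue
            if lo <= pos <= min(lo + 1, hi) or max(hi - 1, lo) <= pos <= hi:
                return True
    return False


def call_start_loss(
    site: SitePanel, gene: GeneModel, reference: Mapping[str, str]
) -> bool:
    """Flag substitutions inside the ATG of *every* isoform (constitutive)."""
    pos = site.pos
    for iso in gene.isoforms:
        first_codon = gene.coding_positions(iso)[:3]
        if pos not in first_codon:
            return False
    return True
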