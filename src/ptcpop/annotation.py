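"""Gene models and annotation quality control.

A :class:`GeneModel` is a gene with one or more isoforms, each an ordered
list of CDS segments in 1-based inclusive reference coordinates, sorted
5'->3' in transcription order (descending genomic coordinates on the minus
strand). Before any variant calling, the gene set is filtered with three
disqualifying rules applied to every isoform:

1. CDS length not a multiple of three;
2. an internal stop codon in the reference translation;
3. start codon != ATG, or stop codon not one of TAA/TAG/TGA.

A gene failing any rule in any isoform is removed. The annotated stop codon
is taken to be the final three nucleotides of the CDS, so rules 2 and 3 are
well defined without UTR information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seq import START_CODON, STOP_CODONS, revcomp, translate

__all__ = ["Isoform", "GeneModel", "qc_filter_genes"]


@dataclass(frozen=True)
class Isoform:
    """One transcript: CDS segments as 1-based inclusive intervals.

    Segments are stored in transcription order; they must not overlap.
    """

    transcript_id: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.transcript_id}: isoform has no CDS segments")
        for lo, hi in self.segments:
            if lo > hi:
                raise ValueError(f"{self.transcript_id}: segment ({lo},{hi}) inverted")

    @property
    def cds_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.segments)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    isoforms: tuple[Isoform, ...]
    is_X: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.isoforms:
            raise ValueError(f"{self.gene_id}: gene has no isoforms")

    # ------------------------------------------------------------------
    # coordinate helpers
    # ------------------------------------------------------------------
    def coding_positions(self, isoform: Isoform) -> np.ndarray:
        """Genomic 1-based positions of the CDS in transcription order."""
        chunks = []
        for lo, hi in isoform.segments:
            if self.strand == "+":
                chunks.append(np.arange(lo, hi + 1))
            else:
                chunks.append(np.arange(hi, lo - 1, -1))
        return np.concatenate(chunks)

    def cds_sequence(self, isoform: Isoform, reference: Mapping[str, str]) -> str:
        """Spliced, strand-oriented CDS sequence (starts with the start codon)."""
        chrom_seq = reference[self.chrom]
        parts = []
        for lo, hi in sorted(isoform.segments):
            if lo < 1 or hi > len(chrom_seq):
                raise ValueError(
                    f"{self.gene_id}: CDS segment ({lo},{hi}) outside chromosome "
                    f"{self.chrom} (length {len(chrom_seq)})"
                )
            parts.append(chrom_seq[lo - 1 : hi])
        cds = "".join(parts)
        return cds if self.strand == "+" else revcomp(cds)

    def span(self) -> tuple[int, int]:
        """Genomic (min, max) coordinate over all isoforms, 1-based inclusive."""
        starts = [lo for iso in self.isoforms for lo, _ in iso.segments]
        ends = [hi for iso in self.isoforms for _, hi in iso.segments]
        return min(starts), max(ends)

    def introns(self, isoform: Isoform) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) in transcription order."""
        out = []
        segs = isoform.segments
        for (a_lo, a_hi), (b_lo, b_hi) in zip(segs, segs[1:]):
            if self.strand == "+":
                out.append((a_hi + 1, b_lo - 1))
            else:
                out.append((b_hi + 1, a_lo - 1))
        return out


# ----------------------------------------------------------------------
# QC filter
# ----------------------------------------------------------------------

def _isoform_errors(gene: GeneModel, isoform: Isoform, reference: Mapping[str, str]) -> list[str]:
    chrom_len = len(reference[gene.chrom])
    for lo, hi in isoform.segments:
        if lo < 1 or hi > chrom_len:
            raise ValueError(
                f"{gene.gene_id}: CDS segment ({lo},{hi}) outside chromosome "
                f"{gene.chrom} (length {chrom_len})"
            )
    errors = []
    if isoform.cds_length % 3:
        errors.append("length")
        return errors  # translation undefined; stop here
    cds = gene.cds_sequence(isoform, reference)
    protein = translate(cds)
    if "*" in protein[:-1]:
        errors.append("internal_stop")
    if cds[:3] != START_CODON or cds[-3:] not in STOP_CODONS:
        errors.append("start_stop")
    return errors


def qc_filter_genes(
    genes: Sequence[GeneModel], reference: Mapping[str, str]
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Apply the three disqualifying annotation rules.

    Returns ``(retained, rejected)`` where ``rejected`` holds
    ``(gene_id, comma-joined reasons)`` pairs. A gene is rejected iff *any*
    isoform fails *any* rule.

    Raises
    ------
    ValueError
        If a gene's coordinates fall outside its chromosome.
    """
    retained: list[GeneModel] = []
    rejected: list[tuple[str, str]] = []
    for gene in genes:
        reasons: list[str] = []
        for iso in gene.isoforms:
            for err in _isoform_errors(gene, iso, reference):
                if err not in reasons:
                    reasons.append(err)
        if reasons:
            rejected.append((gene.gene_id, ",".join(reasons)))
        else:
            retained.append(gene)
    return retained, rejected
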