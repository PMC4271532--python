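"""Reading and writing the standard interchange formats.

FASTA is handled through Biopython, GFF3 through gffutils (in-memory
database). GFF3 coordinates are 1-based inclusive; CDS features are
grouped under mRNA features by Parent/ID attributes. Chromosome-length
strain sequences are read into an ``(n_strains, length)`` byte matrix per
chromosome.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, Isoform

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3",
    "read_strain_panel",
    "write_strain_panel",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene / mRNA / CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            lo, hi = gene.span()
            fh.write(
                f"{gene.chrom}\tptcpop\tgene\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for iso in gene.isoforms:
                t_lo = min(s for s, _ in iso.segments)
                t_hi = max(e for _, e in iso.segments)
                fh.write(
                    f"{gene.chrom}\tptcpop\tmRNA\t{t_lo}\t{t_hi}\t.\t{gene.strand}\t.\t"
                    f"ID={iso.transcript_id};Parent={gene.gene_id}\n"
                )
                for k, (s, e) in enumerate(sorted(iso.segments)):
                    fh.write(
                        f"{gene.chrom}\tptcpop\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                        f"ID={iso.transcript_id}.cds{k};Parent={iso.transcript_id}\n"
                    )


def read_gff3(path: str | Path, x_chrom: str = "X") -> list[GeneModel]:
    """Parse gene models back out of a GFF3 file.

    CDS segments are grouped by their Parent transcript and returned in
    transcription order (descending coordinates on the minus strand).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        isoforms = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            segs = sorted(
                (c.start, c.end) for c in db.children(t, featuretype="CDS")
            )
            if g.strand == "-":
                segs = segs[::-1]
            isoforms.append(Isoform(t.id, tuple(segs)))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                isoforms=tuple(isoforms),
                is_X=g.seqid == x_chrom,
            )
        )
    return genes


def write_strain_panel(
    strain_ids: Sequence[str],
    panel: Mapping[str, np.ndarray],
    directory: str | Path,
) -> list[Path]:
    """One FASTA per strain, one record per chromosome."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(strain_ids):
        seqs = {c: panel[c][i].tobytes().decode() for c in panel}
        p = directory / f"{sid}.fasta"
        write_fasta(seqs, p)
        paths.append(p)
    return paths


def read_strain_panel(
    paths: Sequence[str | Path],
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Read per-strain FASTAs into per-chromosome allele matrices.

    All strains must carry the same chromosomes at identical lengths.
    """
    strain_ids = [Path(p).stem for p in paths]
    per_strain = [read_fasta(p) for p in paths]
    chroms = list(per_strain[0])
    panel: dict[str, np.ndarray] = {}
    for c in chroms:
        lengths = {len(s[c]) for s in per_strain}
        if len(lengths) != 1:
            raise ValueError(f"strain sequences for {c} differ in length")
        panel[c] = np.vstack(
            [np.frombuffer(s[c].encode(), dtype="S1") for s in per_strain]
        )
    return strain_ids, panel
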