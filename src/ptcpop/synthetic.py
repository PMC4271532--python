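"""Self-contained fixture generation with known planted truth.

The generator emulates the structure of a strain-resequencing study:
a reference genome with multi-isoform genes on both strands, per-strain
chromosome-length consensus sequences ("pseudochromosomes") carrying
planted SNPs of chosen functional class and derived allele frequency,
outgroup bases at the polymorphic sites, a gene x (tissue x replicate)
expression matrix with present/absent calls, and a gene-age table with
origination mechanisms and parent links.

Defaults mirror the emulated study design: 162 strains, 30 tissue types
(six of them sex-related) with 4 replicates each. Every generated gene
passes the annotation QC rules by construction: the CDS is a start codon,
non-stop internal codons, and one canonical stop, split across exons at
codon boundaries with GT...AG introns. Additional isoforms skip one
internal exon; because exon boundaries sit on codon boundaries, skipped
isoforms stay in frame and stop-free, and the first/last exons (start and
stop codons) are common to all isoforms.

Heterozygous sites are emitted as IUPAC two-base ambiguity codes, a
documented stand-in for however a real assembly encodes unresolved sites;
the downstream heterozygote filter keys on these codes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import age as age_mod
from .annotation import GeneModel, Isoform
from .seq import CODON_TABLE, IUPAC_PAIR, STOP_CODONS, complement, revcomp

__all__ = [
    "PlantedVariant",
    "SyntheticConfig",
    "generate_reference",
    "generate_strain_panel",
    "generate_outgroups",
    "generate_expression_matrix",
    "generate_age_table",
    "DEFAULT_TISSUES",
    "DEFAULT_SEX_TISSUES",
]

_BASES = "ACGT"
_NONSTOP = sorted(set(CODON_TABLE) - STOP_CODONS)
_STOPS = sorted(STOP_CODONS)

DEFAULT_SEX_TISSUES = (
    "accessory_gland",
    "ejaculatory_duct",
    "ovary",
    "spermatheca",
    "testis",
    "virgin_spermatheca",
)

DEFAULT_TISSUES = (
    "brain",
    "crop",
    "eye",
    "fat_body",
    "head",
    "heart",
    "hindgut",
    "larval_cns",
    "larval_fat_body",
    "larval_hindgut",
    "larval_midgut",
    "larval_salivary_gland",
    "larval_trachea",
    "larval_tubule",
    "male_carcass",
    "female_carcass",
    "midgut",
    "salivary_gland",
    "thoracic_ganglion",
    "tubule",
    "wing_disc",
    "eye_disc",
    "leg_disc",
    "adult_carcass",
) + DEFAULT_SEX_TISSUES

VARIANT_CLASSES = ("nonsense", "missense", "synonymous", "splice", "start_loss")

ARCHETYPES = ("broad", "single_tissue", "sex_restricted", "silent")


@dataclass(frozen=True)
class PlantedVariant:
    """One SNP to plant into the strain panel.

    ``truncation_fraction`` (nonsense only) is the requested fraction of the
    coding region removed in the gene's longest isoform; the realized site
    is the nearest codon admitting a single-base stop gain. With
    ``ancestral_is_ref`` false the reference base is the *derived* allele:
    the outgroups carry the alternate base, so the conservative
    reference-anchored polarization rule leaves the site unpolarized.
    """

    gene_id: str
    site_class: str
    target_daf: float
    constitutive: bool = True
    truncation_fraction: float = 0.5
    ancestral_is_ref: bool = True

    def __post_init__(self) -> None:
        if self.site_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if not 0.0 <= self.target_daf <= 1.0:
            raise ValueError("target_daf outside [0, 1]")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ValueError("truncation_fraction outside [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    n_strains: int = 162
    n_genes: int = 20
    chrom_names: tuple[str, ...] = ("2L", "2R", "3L", "X")
    isoforms_per_gene: tuple[int, int] = (1, 3)
    gene_codons: tuple[int, int] = (60, 150)
    planted_variants: tuple[PlantedVariant, ...] = ()
    outgroup_divergence: float = 0.0
    het_rate: float = 0.0
    n_mask_rate: float = 0.0
    n_tissues: int = 30
    replicates_per_tissue: int = 4
    sex_tissues: tuple[str, ...] | None = None
    expression_archetypes: Mapping[str, str] | None = None
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "broad": 0.55,
            "single_tissue": 0.25,
            "sex_restricted": 0.10,
            "silent": 0.10,
        }
    )
    young_fraction: float = 0.09
    mechanism_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "dna_duplication": 0.79,
            "rna_duplication": 0.11,
            "de_novo": 0.10,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outgroup_divergence", "het_rate", "n_mask_rate", "young_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.n_strains < 60:
            raise ValueError("need at least 60 strains for the informative-base filter")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if "X" not in self.chrom_names or len(self.chrom_names) < 2:
            raise ValueError("chromosomes must include 'X' and at least one autosome")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("invalid isoforms_per_gene range")
        if self.gene_codons[0] < 20:
            raise ValueError("genes need at least 20 codons")

    def tissue_names(self) -> tuple[str, ...]:
        if self.n_tissues == len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES
        return tuple(f"tissue{i + 1:02d}" for i in range(self.n_tissues))

    def sex_tissue_names(self) -> tuple[str, ...]:
        if self.sex_tissues is not None:
            return self.sex_tissues
        tissues = self.tissue_names()
        if tissues == DEFAULT_TISSUES:
            return DEFAULT_SEX_TISSUES
        n_sex = max(1, self.n_tissues // 5)
        return tissues[-n_sex:]


# ----------------------------------------------------------------------
# reference + gene models
# ----------------------------------------------------------------------

def _random_cds_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    body = [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 2)]
    return ["ATG"] + body + [_STOPS[rng.integers(0, len(_STOPS))]]


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` chunks each >= minimum."""
    spare = total - parts * minimum
    cuts = np.sort(rng.integers(0, spare + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [spare]])) + minimum
    return [int(s) for s in sizes]


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    offset: int,
    config: SyntheticConfig,
) -> tuple[str, GeneModel]:
    """Return (genomic fragment, gene model at ``offset``, 0-based)."""
    lo, hi = config.gene_codons
    n_codons = int(rng.integers(lo, hi + 1))
    n_exons = int(rng.integers(2, 5))
    exon_codons = _partition(rng, n_codons, n_exons, 5)
    codons = _random_cds_codons(rng, n_codons)

    # transcription-order layout
    t_parts: list[str] = []
    exon_tspans: list[tuple[int, int]] = []  # [t0, t1) transcription coords
    cursor = 0
    ci = 0
    for k, n_c in enumerate(exon_codons):
        exon_seq = "".join(codons[ci : ci + n_c])
        ci += n_c
        t_parts.append(exon_seq)
        exon_tspans.append((cursor, cursor + len(exon_seq)))
        cursor += len(exon_seq)
        if k < n_exons - 1:
            ilen = int(rng.integers(30, 81))
            intron = "GT" + "".join(
                _BASES[j] for j in rng.integers(0, 4, size=ilen - 4)
            ) + "AG"
            t_parts.append(intron)
            cursor += ilen
    t_seq = "".join(t_parts)
    length = len(t_seq)

    def to_genomic(t0: int, t1: int) -> tuple[int, int]:
        # [t0, t1) transcription -> 1-based inclusive genomic interval
        if strand == "+":
            return offset + t0 + 1, offset + t1
        return offset + length - t1 + 1, offset + length - t0

    # isoforms: first = all exons; extras skip one internal exon each
    n_internal = max(0, n_exons - 2)
    iso_lo, iso_hi = config.isoforms_per_gene
    n_iso = min(int(rng.integers(iso_lo, iso_hi + 1)), 1 + n_internal)
    skippable = list(rng.permutation(np.arange(1, n_exons - 1))[: n_iso - 1])

    isoforms = []
    for t, skip in enumerate([None] + skippable):
        segs = []
        for k, (t0, t1) in enumerate(exon_tspans):
            if skip is not None and k == skip:
                continue
            g = to_genomic(t0, t1)
            segs.append((min(g), max(g)))
        if strand == "-":
            segs = sorted(segs, reverse=True)
        else:
            segs = sorted(segs)
        isoforms.append(Isoform(f"{gene_id}.t{t + 1}", tuple(segs)))

    fragment = t_seq if strand == "+" else revcomp(t_seq)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        isoforms=tuple(isoforms),
        is_X=chrom == "X",
    )
    return fragment, model


def generate_reference(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Reference chromosome sequences and QC-clean gene models.

    Genes are laid out round-robin across chromosomes with random
    intergenic spacers, alternating strands. Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    parts: dict[str, list[str]] = {c: [] for c in config.chrom_names}
    offsets = {c: 0 for c in config.chrom_names}
    genes: list[GeneModel] = []

    def spacer(c: str) -> None:
        n = int(rng.integers(200, 401))
        parts[c].append("".join(_BASES[j] for j in rng.integers(0, 4, size=n)))
        offsets[c] += n

    for c in config.chrom_names:
        spacer(c)
    for i in range(config.n_genes):
        chrom = config.chrom_names[i % len(config.chrom_names)]
        strand = "+-"[i % 2]
        fragment, model = _build_gene(
            rng, f"gene{i + 1:04d}", chrom, strand, offsets[chrom], config
        )
        parts[chrom].append(fragment)
        offsets[chrom] += len(fragment)
        genes.append(model)
        spacer(chrom)
    reference = {c: "".join(parts[c]) for c in config.chrom_names}
    return reference, genes


# ----------------------------------------------------------------------
# site planning for planted variants
# ----------------------------------------------------------------------

def _full_isoform(gene: GeneModel) -> Isoform:
    return max(gene.isoforms, key=lambda iso: iso.cds_length)


def _shared_segments(gene: GeneModel) -> set[tuple[int, int]]:
    shared = set(gene.isoforms[0].segments)
    for iso in gene.isoforms[1:]:
        shared &= set(iso.segments)
    return shared


def _segment_of_positions(iso: Isoform, gene: GeneModel) -> list[tuple[int, int]]:
    """Per coding index (transcription order), the segment containing it."""
    out = []
    for lo, hi in iso.segments:
        out.extend([(lo, hi)] * (hi - lo + 1))
    return out


def _stop_gain_change(codon: str) -> tuple[int, str] | None:
    """First (position, transcription-strand alt base) creating a stop."""
    for within in range(3):
        for b in _BASES:
            if b == codon[within]:
                continue
            if CODON_TABLE[codon[:within] + b + codon[within + 1 :]] == "*":
                return within, b
    return None


def _coding_change(codon: str, synonymous: bool) -> tuple[int, str] | None:
    aa = CODON_TABLE[codon]
    for within in (2, 1, 0):
        for b in _BASES:
            if b == codon[within]:
                continue
            mutant_aa = CODON_TABLE[codon[:within] + b + codon[within + 1 :]]
            if mutant_aa == "*":
                continue
            if (mutant_aa == aa) == synonymous:
                return within, b
    return None


class SitePlanner:
    """Turns planted-variant requests into concrete genomic substitutions."""

    def __init__(self, reference: Mapping[str, str], genes: Sequence[GeneModel]):
        self.reference = reference
        self.genes = {g.gene_id: g for g in genes}
        self.used: set[tuple[str, int]] = set()

    def _reserve(self, chrom: str, pos: int) -> None:
        key = (chrom, pos)
        if key in self.used:
            raise ValueError(f"planted sites collide at {chrom}:{pos}")
        self.used.add(key)

    def plan(self, pv: PlantedVariant, rng: np.random.Generator) -> dict:
        gene = self.genes[pv.gene_id]
        if pv.site_class == "nonsense":
            return self._plan_nonsense(pv, gene)
        if pv.site_class in ("missense", "synonymous"):
            return self._plan_coding(pv, gene, rng)
        if pv.site_class == "splice":
            return self._plan_splice(pv, gene, rng)
        return self._plan_start_loss(pv, gene)

    # -- helpers ------------------------------------------------------
    def _emit(self, pv: PlantedVariant, gene: GeneModel, pos: int, alt: str) -> dict:
        self._reserve(gene.chrom, pos)
        ref = self.reference[gene.chrom][pos - 1]
        truncs = _isoform_truncations(gene, self.reference, pos, alt)
        finite = [t for t in truncs.values() if t is not None]
        constitutive = len(finite) == len(gene.isoforms) and len(finite) > 0
        return {
            "chrom": gene.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene_id": gene.gene_id,
            "site_class": pv.site_class,
            "constitutive": constitutive if pv.site_class == "nonsense" else pv.constitutive,
            "min_truncation": min(finite) if constitutive and finite else np.nan,
            "target_daf": pv.target_daf,
            "ancestral_is_ref": pv.ancestral_is_ref,
        }

    def _candidate_codons(
        self, gene: GeneModel, allowed: set[tuple[int, int]]
    ) -> tuple[Isoform, np.ndarray, str, list[int]]:
        full = _full_isoform(gene)
        positions = gene.coding_positions(full)
        cds = gene.cds_sequence(full, self.reference)
        seg_of = _segment_of_positions(full, gene)
        n_codons = len(cds) // 3
        candidates = []
        for i in range(1, n_codons - 1):
            segs = {seg_of[i * 3 + k] for k in range(3)}
            if not segs <= allowed:
                continue
            if any((gene.chrom, int(positions[i * 3 + k])) in self.used for k in range(3)):
                continue
            candidates.append(i)
        return full, positions, cds, candidates

    def _plan_nonsense(self, pv: PlantedVariant, gene: GeneModel) -> dict:
        if pv.constitutive:
            allowed = _shared_segments(gene)
        else:
            allowed = set(_full_isoform(gene).segments) - _shared_segments(gene)
            if not allowed:
                raise ValueError(
                    f"{gene.gene_id}: non-constitutive nonsense needs a skippable exon"
                )
        full, positions, cds, candidates = self._candidate_codons(gene, allowed)
        n_codons = len(cds) // 3
        desired = int(round((n_codons - 1) * (1.0 - pv.truncation_fraction)))
        desired = min(max(desired, 1), n_codons - 2)
        for i in sorted(candidates, key=lambda i: (abs(i - desired), i)):
            change = _stop_gain_change(cds[i * 3 : i * 3 + 3])
            if change is None:
                continue
            within, alt_t = change
            pos = int(positions[i * 3 + within])
            alt = alt_t if gene.strand == "+" else complement(alt_t)
            return self._emit(pv, gene, pos, alt)
        raise ValueError(f"{gene.gene_id}: no codon admits a stop-gain substitution")

    def _plan_coding(
        self, pv: PlantedVariant, gene: GeneModel, rng: np.random.Generator
    ) -> dict:
        full, positions, cds, candidates = self._candidate_codons(
            gene, _shared_segments(gene)
        )
        order = list(rng.permutation(candidates))
        for i in order:
            change = _coding_change(
                cds[i * 3 : i * 3 + 3], synonymous=pv.site_class == "synonymous"
            )
            if change is None:
                continue
            within, alt_t = change
            pos = int(positions[i * 3 + within])
            alt = alt_t if gene.strand == "+" else complement(alt_t)
            return self._emit(pv, gene, pos, alt)
        raise ValueError(f"{gene.gene_id}: no {pv.site_class} substitution found")

    def _plan_splice(
        self, pv: PlantedVariant, gene: GeneModel, rng: np.random.Generator
    ) -> dict:
        full = _full_isoform(gene)
        introns = gene.introns(full)
        order = list(rng.permutation(len(introns)))
        for j in order:
            lo, hi = introns[j]
            pos = lo if gene.strand == "+" else hi  # donor-side first base ('G')
            if (gene.chrom, pos) in self.used:
                continue
            alt = "A" if gene.strand == "+" else "T"  # G->A in transcription orientation
            return self._emit(pv, gene, pos, alt)
        raise ValueError(f"{gene.gene_id}: no free intron for a splice variant")

    def _plan_start_loss(self, pv: PlantedVariant, gene: GeneModel) -> dict:
        full = _full_isoform(gene)
        pos = int(gene.coding_positions(full)[0])  # the 'A' of ATG
        alt = "G" if gene.strand == "+" else "C"  # A->G in transcription orientation
        return self._emit(pv, gene, pos, alt)


def _isoform_truncations(
    gene: GeneModel, reference: Mapping[str, str], pos: int, alt: str
) -> dict[str, float | None]:
    """Truncation fraction per isoform if the change is a stop gain there."""
    out: dict[str, float | None] = {}
    alt_t = alt if gene.strand == "+" else complement(alt)
    for iso in gene.isoforms:
        positions = gene.coding_positions(iso)
        hits = np.flatnonzero(positions == pos)
        if hits.size == 0:
            out[iso.transcript_id] = None
            continue
        idx = int(hits[0])
        cds = gene.cds_sequence(iso, reference)
        codon_i, within = idx // 3, idx % 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        mutant = codon[:within] + alt_t + codon[within + 1 :]
        if CODON_TABLE[codon] != "*" and CODON_TABLE[mutant] == "*":
            n_codons = len(cds) // 3
            out[iso.transcript_id] = (n_codons - (codon_i + 1)) / (n_codons - 1)
        else:
            out[iso.transcript_id] = None
    return out


# ----------------------------------------------------------------------
# strain panel
# ----------------------------------------------------------------------

def generate_strain_panel(
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
) -> tuple[list[str], dict[str, np.ndarray], pd.DataFrame]:
    """Per-strain pseudochromosomes plus the planted-truth table.

    Returns ``(strain_ids, panel, truth)`` where ``panel`` maps chromosome
    to an ``(n_strains, length)`` byte matrix. Each planted variant is
    realized in ``round(target_daf * n_strains)`` strains; heterozygote
    codes and N masks are then injected independently per strain and site
    at the configured rates (planted sites included - noise is noise).
    """
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_strains
    strain_ids = [f"strain{i + 1:03d}" for i in range(n)]
    panel = {
        c: np.tile(np.frombuffer(seq.encode(), dtype="S1"), (n, 1))
        for c, seq in reference.items()
    }
    planner = SitePlanner(reference, genes)
    rows = []
    for pv in config.planted_variants:
        site = planner.plan(pv, rng)
        k = int(round(pv.target_daf * n))
        carriers = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
        col = panel[site["chrom"]][:, site["pos"] - 1]
        alt_b = site["alt"].encode()
        if pv.ancestral_is_ref:
            col[carriers] = alt_b
            derived, ancestral = site["alt"], site["ref"]
        else:
            mask = np.ones(n, dtype=bool)
            mask[carriers] = False
            col[mask] = alt_b
            derived, ancestral = site["ref"], site["alt"]
        site.update(derived=derived, ancestral=ancestral, n_derived=k)
        rows.append(site)
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "site_class", "constitutive",
            "min_truncation", "target_daf", "ancestral_is_ref", "derived",
            "ancestral", "n_derived",
        ],
    )

    if config.het_rate or config.n_mask_rate:
        het, nmask = config.het_rate, config.n_mask_rate
        for chrom, mat in panel.items():
            for s in range(n):
                r = rng.random(mat.shape[1])
                het_idx = np.flatnonzero(r < het)
                n_idx = np.flatnonzero((r >= het) & (r < het + nmask))
                for j in het_idx:
                    base = mat[s, j].decode()
                    if base not in _BASES:
                        continue
                    other = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
                    mat[s, j] = IUPAC_PAIR[frozenset((base, other))].encode()
                mat[s, n_idx] = b"N"
    return strain_ids, panel, truth


def generate_outgroups(
    reference: Mapping[str, str],
    truth: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Outgroup base table (two outgroups) at every planted site.

    Polarizable sites (``ancestral_is_ref``) get the ancestral (reference)
    base in both outgroups; otherwise both outgroups carry the alternate
    allele, violating the reference-anchored rule. Each outgroup base is
    then independently substituted with probability ``outgroup_divergence``.
    """
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    for rec in truth.itertuples():
        bases = []
        for _ in range(2):
            b = rec.ancestral
            if rng.random() < config.outgroup_divergence:
                b = _BASES[(_BASES.index(b) + int(rng.integers(1, 4))) % 4]
            bases.append(b)
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "outgroup1": bases[0], "outgroup2": bases[1]}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "outgroup1", "outgroup2"])


# ----------------------------------------------------------------------
# canned planted-recovery experiment
# ----------------------------------------------------------------------

def recovery_roster(
    genes: Sequence[GeneModel], reference: Mapping[str, str]
) -> tuple[PlantedVariant, ...]:
    """A class-spanning planted roster for end-to-end recovery studies.

    One variant per gene: constitutive nonsense across a range of DAFs
    (including values straddling the 1.5% and 10% group boundaries) and
    truncation targets, low-truncation and non-constitutive nonsense
    negatives, missense/synonymous/splice/start-loss controls, and a pair
    of deliberately unpolarizable sites. Each request is dry-planned
    against the actual gene structures, skipping genes that cannot host it
    (e.g. isoform-shared exons without a single-base stop gain). Requires
    roughly >= 80 genes so that every slot can be filled.
    """
    multi = [g.gene_id for g in genes if len(g.isoforms) >= 2]
    single_or_any = [
        g.gene_id for g in genes if g.gene_id not in set(multi[:10])
    ]
    if len(genes) < 80 or len(multi) < 10:
        raise ValueError("roster needs >= 80 genes with >= 10 multi-isoform genes")

    trial = SitePlanner(reference, genes)
    trial_rng = np.random.default_rng(0)
    roster: list[PlantedVariant] = []

    def place(requests: list[PlantedVariant], pool: list[str]) -> None:
        """Assign each request to the next feasible gene in ``pool``."""
        it = iter(pool)
        for pv in requests:
            while True:
                gid = next(it)
                candidate = PlantedVariant(
                    gid, pv.site_class, pv.target_daf, pv.constitutive,
                    pv.truncation_fraction, pv.ancestral_is_ref,
                )
                try:
                    trial.plan(candidate, trial_rng)
                except ValueError:
                    continue
                roster.append(candidate)
                break

    dafs = (0.01, 0.02, 0.05, 0.10, 0.11, 0.30, 0.50, 0.02, 0.10, 0.01)
    truncs = (0.06, 0.20, 0.50, 0.80, 0.95)
    requests = [
        # constitutive nonsense across DAFs and truncations
        PlantedVariant("?", "nonsense", dafs[i % len(dafs)],
                       truncation_fraction=truncs[i % len(truncs)])
        for i in range(20)
    ]
    # tiny truncation targets: mostly below the 5% rule
    requests += [
        PlantedVariant("?", "nonsense", 0.05, truncation_fraction=0.02)
        for _ in range(5)
    ]
    requests += [PlantedVariant("?", "missense", dafs[i % len(dafs)]) for i in range(10)]
    requests += [PlantedVariant("?", "synonymous", dafs[i % len(dafs)]) for i in range(10)]
    requests += [PlantedVariant("?", "splice", 0.10) for _ in range(5)]
    requests += [PlantedVariant("?", "start_loss", 0.05) for _ in range(3)]
    # outgroups carry the alternate allele: unpolarizable downstream
    requests += [
        PlantedVariant("?", "nonsense", 0.30, truncation_fraction=0.5,
                       ancestral_is_ref=False)
        for _ in range(2)
    ]
    place(requests, single_or_any)
    # nonsense in a skippable exon: not constitutive
    place(
        [PlantedVariant("?", "nonsense", 0.20, constitutive=False,
                        truncation_fraction=0.5) for _ in range(5)],
        multi,
    )
    return tuple(roster)


def recovery_experiment(config: SyntheticConfig):
    """Generate a full planted study: reference, panel, truth, outgroups.

    The roster is chosen after the reference so that non-constitutive
    plants land on multi-isoform genes; the reference itself does not
    depend on the planted variants. Returns
    ``(config, reference, genes, strain_ids, panel, truth, outgroups)``.
    """
    from dataclasses import replace

    reference, genes = generate_reference(config)
    cfg = replace(config, planted_variants=recovery_roster(genes, reference))
    strain_ids, panel, truth = generate_strain_panel(reference, genes, cfg)
    outgroups = generate_outgroups(reference, truth, cfg)
    return cfg, reference, genes, strain_ids, panel, truth, outgroups


# ----------------------------------------------------------------------
# expression matrix
# ----------------------------------------------------------------------

def generate_expression_matrix(
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Linear-scale gene x (tissue, replicate) values with present calls.

    Archetypes: ``broad`` (present everywhere), ``single_tissue`` (present
    in one tissue), ``sex_restricted`` (present in the sex-related tissues
    only), ``silent`` (absent everywhere). Replicates are noisy copies;
    present calls are consistent across replicates of a tissue. Returns
    ``(values, present, archetypes)``.
    """
    rng = np.random.default_rng([config.seed, 4])
    tissues = config.tissue_names()
    sex = set(config.sex_tissue_names())
    reps = range(1, config.replicates_per_tissue + 1)
    columns = pd.MultiIndex.from_product(
        [tissues, [f"rep{r}" for r in reps]], names=["tissue", "replicate"]
    )
    gene_ids = [g.gene_id for g in genes]

    names = list(config.archetype_fractions)
    probs = np.array([config.archetype_fractions[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    archetypes = {}
    for gid in gene_ids:
        if config.expression_archetypes and gid in config.expression_archetypes:
            archetypes[gid] = config.expression_archetypes[gid]
        else:
            archetypes[gid] = names[rng.choice(len(names), p=probs)]

    values = np.empty((len(gene_ids), len(columns)))
    present = np.zeros((len(gene_ids), len(columns)), dtype=bool)
    n_rep = config.replicates_per_tissue
    for gi, gid in enumerate(gene_ids):
        arch = archetypes[gid]
        if arch == "broad":
            levels = 10.0 ** rng.normal(2.5, 0.4, size=len(tissues))
            expressed = np.ones(len(tissues), dtype=bool)
        elif arch == "single_tissue":
            levels = np.full(len(tissues), 8.0)
            t0 = int(rng.integers(len(tissues)))
            levels[t0] = 10.0 ** rng.normal(3.0, 0.2)
            expressed = np.zeros(len(tissues), dtype=bool)
            expressed[t0] = True
        elif arch == "sex_restricted":
            expressed = np.array([t in sex for t in tissues])
            levels = np.where(expressed, 10.0 ** rng.normal(2.8, 0.3, len(tissues)), 8.0)
        elif arch == "silent":
            levels = np.full(len(tissues), 6.0)
            expressed = np.zeros(len(tissues), dtype=bool)
        else:
            raise ValueError(f"unknown archetype {arch!r}")
        noise = 10.0 ** rng.normal(0.0, 0.05, size=(len(tissues), n_rep))
        values[gi] = (levels[:, None] * noise).ravel()
        present[gi] = np.repeat(expressed, n_rep)

    values_df = pd.DataFrame(values, index=gene_ids, columns=columns)
    present_df = pd.DataFrame(present, index=gene_ids, columns=columns)
    return values_df, present_df, pd.Series(archetypes, name="archetype")


# ----------------------------------------------------------------------
# age table
# ----------------------------------------------------------------------

def generate_age_table(
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
    preset: str | None = None,
) -> list[age_mod.AgeRecord]:
    """Branch / mechanism / parent-link assignment per gene.

    With ``preset="table2"`` the gene list is ignored and the packaged
    printed-counts fixture is expanded instead (see
    :func:`ptcpop.age.table2_dataset`); use that function directly when the
    PTC group labels are also needed.
    """
    if preset == "table2":
        records, _ = age_mod.table2_dataset()
        return records
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng([config.seed, 5])
    gene_ids = [g.gene_id for g in genes]
    mech_names = list(config.mechanism_fractions)
    mech_probs = np.array([config.mechanism_fractions[m] for m in mech_names])
    mech_probs = mech_probs / mech_probs.sum()

    branches = {}
    for gid in gene_ids:
        if rng.random() < config.young_fraction:
            branches[gid] = int(rng.integers(1, 7))
        else:
            branches[gid] = int(rng.integers(-5, 1))
    records = []
    for gid in gene_ids:
        branch = branches[gid]
        young = branch >= 1
        mechanism = "none"
        parent = None
        strict = False
        if young:
            mechanism = mech_names[rng.choice(len(mech_names), p=mech_probs)]
            if mechanism in ("dna_duplication", "rna_duplication") and len(gene_ids) > 1:
                parent = gene_ids[int(rng.integers(len(gene_ids)))]
                while parent == gid:
                    parent = gene_ids[int(rng.integers(len(gene_ids)))]
                strict = branches[parent] < branch
        records.append(
            age_mod.AgeRecord(
                gene_id=gid,
                branch=branch,
                young=young,
                mechanism=mechanism,
                parent_gene=parent,
                strict_parent_child=strict,
            )
        )
    return records
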