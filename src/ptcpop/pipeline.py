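"""End-to-end variant discovery over a strain panel.

Scans the pseudochromosome panel for segregating sites, applies the site
filters, classifies every in-gene SNP, calls constitutive PTCs, splice and
start-codon disruptions, polarizes against the outgroup table, and emits a
tidy per-site table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .polarize import assign_frequency_group, compute_daf, infer_ancestral
from .variants import (
    MIN_INFORMATIVE,
    MIN_TRUNCATION,
    SitePanel,
    call_constitutive_ptc,
    call_splice_disruption,
    call_start_loss,
    classify_coding_snp,
    site_filters,
)

__all__ = ["discover_variants", "accepted_ptcs"]

VARIANT_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "GENE", "CLASS", "CONSTITUTIVE",
    "MIN_TRUNCATION", "PTC", "PTC_REASON", "SPLICE", "START_LOSS",
    "FILTER", "ANC", "DER", "N_DER", "N_INF", "DAF", "GROUP",
]


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        lo, hi = gene.span()
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi + 1, gene)
    return trees


def _candidate_positions(mat: np.ndarray, ref_row: np.ndarray) -> np.ndarray:
    """Columns where some strain carries an unambiguous non-reference base."""
    acgt = np.isin(mat, np.frombuffer(b"ACGT", dtype="S1"))
    diff = acgt & (mat != ref_row)
    return np.flatnonzero(diff.any(axis=0))


def discover_variants(
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    panel: Mapping[str, np.ndarray],
    outgroups: pd.DataFrame | None = None,
    min_informative: int = MIN_INFORMATIVE,
    min_truncation: float = MIN_TRUNCATION,
) -> pd.DataFrame:
    """Scan, filter, classify, and polarize every segregating site.

    ``outgroups`` is a table with columns chrom/pos/outgroup1/outgroup2;
    sites absent from it stay unpolarized (empty ANC/DER, NaN DAF). Sites
    failing a filter are kept with the FILTER column set and no class
    assigned. Intergenic sites are reported with an empty GENE.
    """
    trees = _gene_trees(genes)
    og: dict[tuple[str, int], tuple[str, str]] = {}
    if outgroups is not None:
        for rec in outgroups.itertuples():
            og[(rec.chrom, int(rec.pos))] = (rec.outgroup1, rec.outgroup2)

    rows = []
    for chrom, mat in panel.items():
        ref_row = np.frombuffer(reference[chrom].encode(), dtype="S1")
        for j in _candidate_positions(mat, ref_row):
            pos = int(j) + 1
            ref_base = ref_row[j].decode()
            site = SitePanel(
                chrom=chrom,
                pos=pos,
                ref_base=ref_base,
                strain_alleles=tuple(b.decode() for b in mat[:, j]),
            )
            passed, reason = site_filters(site, min_informative)
            row = {c: "" for c in VARIANT_COLUMNS}
            row.update(
                CHROM=chrom, POS=pos, REF=ref_base, FILTER=reason if not passed else "PASS",
                CONSTITUTIVE=False, PTC=False, SPLICE=False, START_LOSS=False,
                MIN_TRUNCATION=np.nan, N_DER=np.nan, N_INF=np.nan, DAF=np.nan,
            )
            if not passed:
                rows.append(row)
                continue
            alt = next(a for a in site.informative if a != ref_base)
            row["ALT"] = alt
            hits = trees.get(chrom, IntervalTree())[pos] if chrom in trees else set()
            if hits:
                gene = sorted(hits, key=lambda iv: iv.data.gene_id)[0].data
                snp = classify_coding_snp(site, gene, reference, alt=alt)
                accepted, ptc_reason = call_constitutive_ptc(snp, min_truncation)
                row.update(
                    GENE=gene.gene_id,
                    CLASS=snp.site_class,
                    CONSTITUTIVE=snp.constitutive,
                    MIN_TRUNCATION=snp.min_truncation,
                    PTC=accepted,
                    PTC_REASON=ptc_reason,
                    SPLICE=call_splice_disruption(site, gene, reference),
                    START_LOSS=call_start_loss(site, gene, reference),
                )
            else:
                row["CLASS"] = "intergenic"
            bases = og.get((chrom, pos))
            derived = infer_ancestral(ref_base, alt, *(bases or (None, None)))
            if derived is not None:
                n_der, n_inf, daf = compute_daf(site, derived)
                row.update(
                    ANC=ref_base if derived == alt else alt,
                    DER=derived,
                    N_DER=n_der,
                    N_INF=n_inf,
                    DAF=daf,
                    GROUP=assign_frequency_group(daf) if n_der else "",
                )
            rows.append(row)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return df.sort_values(["CHROM", "POS"], kind="mergesort").reset_index(drop=True)


def accepted_ptcs(variants: pd.DataFrame) -> pd.DataFrame:
    """Subset of discovered variants accepted as constitutive PTCs."""
    return variants[variants["PTC"]].reset_index(drop=True)


def evaluate_recovery(
    variants: pd.DataFrame,
    truth: pd.DataFrame,
    min_truncation: float = MIN_TRUNCATION,
) -> dict[str, float]:
    """Score discovered PTC calls against a planted-truth table.

    Expected positives are the planted constitutive nonsense variants whose
    recorded minimum truncation passes the 5% rule. Reports sensitivity,
    the number of PTC calls at unexpected sites, the worst absolute DAF
    error over polarized planted sites, and the number of frequency-group
    mismatches against the planted allele counts.
    """
    expected = truth[
        (truth["site_class"] == "nonsense")
        & truth["constitutive"]
        & (truth["min_truncation"] >= min_truncation)
    ]
    expected_keys = set(zip(expected["chrom"], expected["pos"]))
    called = variants[variants["PTC"]]
    called_keys = set(zip(called["CHROM"], called["POS"]))
    n_true = len(expected_keys & called_keys)

    daf_errors = []
    group_mismatches = 0
    polarized = variants[variants["DAF"].notna()]
    by_key = {(r.chrom, r.pos): r for r in truth.itertuples()}
    for rec in polarized.itertuples():
        t = by_key.get((rec.CHROM, rec.POS))
        if t is None or not t.ancestral_is_ref:
            continue
        daf_errors.append(abs(rec.DAF - t.target_daf))
        if rec.GROUP and rec.N_INF:
            planted_daf = t.n_derived / rec.N_INF
            from .polarize import assign_frequency_group

            if assign_frequency_group(planted_daf) != rec.GROUP:
                group_mismatches += 1
    return {
        "n_expected": float(len(expected_keys)),
        "n_called": float(len(called_keys)),
        "sensitivity": n_true / len(expected_keys) if expected_keys else float("nan"),
        "n_false_calls": float(len(called_keys - expected_keys)),
        "max_daf_error": max(daf_errors) if daf_errors else float("nan"),
        "n_group_mismatches": float(group_mismatches),
    }
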