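"""Synthetic fixture generator: determinism, round-trips, planted truth."""

import numpy as np
import pandas as pd
import pytest

from ptcpop import io
from ptcpop import synthetic as syn
from ptcpop.annotation import qc_filter_genes
from ptcpop.seq import HET_CODES
from ptcpop.variants import classify_coding_snp, SitePanel


class TestConfigValidation:
    def test_defaults_mirror_study_design(self):
        cfg = syn.SyntheticConfig()
        assert cfg.n_strains == 162
        assert cfg.n_tissues == 30
        assert cfg.replicates_per_tissue == 4
        assert len(cfg.sex_tissue_names()) == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_strains": 40},
            {"chrom_names": ("2L", "2L", "X")},
            {"chrom_names": ("2L", "3R")},
            {"het_rate": 1.5},
            {"isoforms_per_gene": (3, 1)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.SyntheticConfig(**kwargs)


class TestReference:
    def test_every_gene_qc_clean(self, small_reference):
        reference, genes = small_reference
        retained, rejected = qc_filter_genes(genes, reference)
        assert not rejected and len(retained) == len(genes)

    def test_both_strands_and_x_flag(self, small_reference):
        _, genes = small_reference
        assert {g.strand for g in genes} == {"+", "-"}
        assert any(g.is_X for g in genes)
        for g in genes:
            assert g.is_X == (g.chrom == "X")

    def test_seeded_determinism_byte_identical(self, tmp_path, small_config):
        paths = []
        for run in ("a", "b"):
            ref, genes = syn.generate_reference(small_config)
            fasta = tmp_path / f"{run}.fasta"
            gff = tmp_path / f"{run}.gff3"
            io.write_fasta(ref, fasta)
            io.write_gff3(genes, gff)
            paths.append((fasta.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_round_trip_cds_reproduced(self, tmp_path, small_reference):
        reference, genes = small_reference
        io.write_fasta(reference, tmp_path / "r.fasta")
        io.write_gff3(genes, tmp_path / "a.gff3")
        ref2 = io.read_fasta(tmp_path / "r.fasta")
        genes2 = {g.gene_id: g for g in io.read_gff3(tmp_path / "a.gff3")}
        for g in genes:
            h = genes2[g.gene_id]
            for iso_a, iso_b in zip(g.isoforms, h.isoforms):
                assert g.cds_sequence(iso_a, reference) == h.cds_sequence(iso_b, ref2)

    def test_infeasible_gene_length_raises(self):
        with pytest.raises(ValueError):
            syn.SyntheticConfig(gene_codons=(5, 10))


class TestStrainPanel:
    def _panel(self, planted, n_strains=100, seed=5, **kwargs):
        cfg = syn.SyntheticConfig(
            n_genes=10, n_strains=n_strains, seed=seed,
            planted_variants=tuple(planted), **kwargs,
        )
        ref, genes = syn.generate_reference(cfg)
        sids, panel, truth = syn.generate_strain_panel(ref, genes, cfg)
        return cfg, ref, genes, sids, panel, truth

    def test_no_variants_panel_equals_reference(self):
        cfg, ref, genes, sids, panel, truth = self._panel([])
        for c, mat in panel.items():
            expected = np.frombuffer(ref[c].encode(), dtype="S1")
            assert (mat == expected).all()
        assert truth.empty

    def test_exact_daf_realization(self):
        pv = syn.PlantedVariant("gene0001", "nonsense", 0.30)
        cfg, ref, genes, sids, panel, truth = self._panel([pv])
        row = truth.iloc[0]
        col = panel[row.chrom][:, row.pos - 1]
        assert (col == row.alt.encode()).sum() == 30
        assert row.n_derived == 30

    def test_derived_is_reference_when_ancestral_is_alt(self):
        pv = syn.PlantedVariant("gene0001", "nonsense", 0.30, ancestral_is_ref=False)
        cfg, ref, genes, sids, panel, truth = self._panel([pv])
        row = truth.iloc[0]
        col = panel[row.chrom][:, row.pos - 1]
        assert row.derived == row.ref
        assert (col == row.ref.encode()).sum() == 30

    def test_planted_class_verified_by_classifier(self):
        planted = [
            syn.PlantedVariant("gene0001", "nonsense", 0.1, truncation_fraction=0.6),
            syn.PlantedVariant("gene0002", "synonymous", 0.1),
            syn.PlantedVariant("gene0003", "missense", 0.1),
        ]
        cfg, ref, genes, sids, panel, truth = self._panel(planted)
        by_id = {g.gene_id: g for g in genes}
        for row in truth.itertuples():
            site = SitePanel(
                chrom=row.chrom, pos=row.pos, ref_base=row.ref,
                strain_alleles=tuple(
                    b.decode() for b in panel[row.chrom][:, row.pos - 1]
                ),
            )
            snp = classify_coding_snp(site, by_id[row.gene_id], ref, alt=row.alt)
            assert snp.site_class == row.site_class
            if row.site_class == "nonsense":
                assert snp.constitutive == row.constitutive
                assert snp.min_truncation == pytest.approx(row.min_truncation)

    def test_requested_truncation_approximated(self):
        # single-isoform genes: no shared-exon constraint on codon choice
        pv = syn.PlantedVariant("gene0002", "nonsense", 0.1, truncation_fraction=0.25)
        cfg, ref, genes, sids, panel, truth = self._panel(
            [pv], isoforms_per_gene=(1, 1)
        )
        assert truth.iloc[0].min_truncation == pytest.approx(0.25, abs=0.1)

    def test_het_and_n_masks_injected(self):
        cfg, ref, genes, sids, panel, truth = self._panel(
            [], het_rate=0.01, n_mask_rate=0.02
        )
        all_bytes = np.concatenate([m.ravel() for m in panel.values()])
        n_total = all_bytes.size
        n_n = (all_bytes == b"N").sum()
        het_set = {c.encode() for c in HET_CODES}
        n_het = sum((all_bytes == h).sum() for h in het_set)
        assert n_n / n_total == pytest.approx(0.02, rel=0.1)
        assert n_het / n_total == pytest.approx(0.01, rel=0.1)

    def test_panel_deterministic(self):
        pv = syn.PlantedVariant("gene0001", "missense", 0.2)
        _, _, _, _, p1, t1 = self._panel([pv], seed=9)
        _, _, _, _, p2, t2 = self._panel([pv], seed=9)
        assert t1.equals(t2)
        for c in p1:
            assert (p1[c] == p2[c]).all()


class TestOutgroups:
    def test_zero_divergence_all_polarizable(self):
        cfg = syn.SyntheticConfig(
            n_genes=6, n_strains=100, seed=2,
            planted_variants=(
                syn.PlantedVariant("gene0001", "nonsense", 0.2),
                syn.PlantedVariant("gene0002", "synonymous", 0.4),
            ),
        )
        ref, genes = syn.generate_reference(cfg)
        _, _, truth = syn.generate_strain_panel(ref, genes, cfg)
        og = syn.generate_outgroups(ref, truth, cfg)
        merged = truth.merge(og, on=["chrom", "pos"])
        assert (merged.outgroup1 == merged.ref).all()
        assert (merged.outgroup2 == merged.ref).all()

    def test_unpolarizable_site_violates_reference_anchor(self):
        cfg = syn.SyntheticConfig(
            n_genes=6, n_strains=100, seed=2,
            planted_variants=(
                syn.PlantedVariant("gene0001", "nonsense", 0.2, ancestral_is_ref=False),
            ),
        )
        ref, genes = syn.generate_reference(cfg)
        _, _, truth = syn.generate_strain_panel(ref, genes, cfg)
        og = syn.generate_outgroups(ref, truth, cfg)
        merged = truth.merge(og, on=["chrom", "pos"])
        assert (merged.outgroup1 != merged.ref).all()

    def test_seeded_reproducibility(self):
        cfg = syn.SyntheticConfig(
            n_genes=6, n_strains=100, seed=2, outgroup_divergence=0.3,
            planted_variants=tuple(
                syn.PlantedVariant(f"gene{i:04d}", "synonymous", 0.2)
                for i in range(1, 5)
            ),
        )
        ref, genes = syn.generate_reference(cfg)
        _, _, truth = syn.generate_strain_panel(ref, genes, cfg)
        assert syn.generate_outgroups(ref, truth, cfg).equals(
            syn.generate_outgroups(ref, truth, cfg)
        )


@pytest.fixture(scope="module")
def matrix():
    cfg = syn.SyntheticConfig(
        n_genes=40, n_strains=100, seed=6,
        expression_archetypes={
            "gene0001": "silent",
            "gene0002": "single_tissue",
            "gene0003": "broad",
            "gene0004": "sex_restricted",
        },
    )
    ref, genes = syn.generate_reference(cfg)
    values, present, archetypes = syn.generate_expression_matrix(genes, cfg)
    return cfg, values, present, archetypes


class TestExpressionGenerator:
    def test_silent_gene_no_present_calls(self, matrix):
        _, values, present, _ = matrix
        assert present.loc["gene0001"].sum() == 0

    def test_single_tissue_tau_one_downstream(self, matrix):
        from ptcpop.expression import quantile_normalize_profiles, compute_tau

        _, values, present, _ = matrix
        prof = quantile_normalize_profiles(values, present)
        assert compute_tau(prof.loc["gene0002"].to_numpy()) == pytest.approx(1.0)

    def test_broad_gene_present_everywhere(self, matrix):
        cfg, values, present, _ = matrix
        assert present.loc["gene0003"].all()

    def test_sex_restricted_present_only_in_sex_tissues(self, matrix):
        cfg, values, present, _ = matrix
        from ptcpop.expression import tissue_present

        tp = tissue_present(present).loc["gene0004"]
        sex = set(cfg.sex_tissue_names())
        assert set(tp[tp].index) == sex

    def test_values_positive_linear_scale(self, matrix):
        _, values, _, _ = matrix
        assert (values.to_numpy() > 0).all()


class TestAgeGenerator:
    def test_table2_preset_counts(self):
        cfg = syn.SyntheticConfig(n_genes=5, n_strains=100)
        records = syn.generate_age_table([], cfg, preset="table2")
        old_free = [r for r in records if not r.young]
        assert len(records) == 10580 + 460 + 74 + 7 + 764 + 89 + 32 + 7

    def test_table2_preset_low_frequency_young_count(self):
        from ptcpop.age import table2_dataset

        records, groups = table2_dataset()
        young_low = [
            r for r in records if r.young and groups.get(r.gene_id) == "low"
        ]
        assert len(young_low) == 89

    def test_mechanisms_none_for_old_genes(self, small_reference, small_config):
        _, genes = small_reference
        records = syn.generate_age_table(genes, small_config)
        for r in records:
            if not r.young:
                assert r.mechanism == "none" and r.parent_gene is None

    def test_strict_flag_requires_older_parent(self, small_reference, small_config):
        _, genes = small_reference
        cfg = syn.SyntheticConfig(
            n_genes=small_config.n_genes, n_strains=100, seed=4, young_fraction=0.5
        )
        records = syn.generate_age_table(genes, cfg)
        branches = {r.gene_id: r.branch for r in records}
        for r in records:
            if r.strict_parent_child:
                assert branches[r.parent_gene] < r.branch
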