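"""Generator determinism, label conservation and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from ligandshift.errors import ConfigError, DependencyError
from ligandshift.proteome import differential_expression
from ligandshift.simulate import (GroundTruth, SimulationConfig, simulate_all,
                                  simulate_aqua, simulate_immunopeptidome,
                                  simulate_proteome, simulate_variants)
from ligandshift.variants import apply_variants


class TestConfigValidation:
    def test_de_count_exceeding_proteins_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_proteins=10, n_de_proteins=11)

    @pytest.mark.parametrize("field,value", [
        ("frac_processing_shift", 1.5),
        ("missingness", -0.1),
        ("n_proteins", 0),
        ("de_log2fc", -1.0),
    ])
    def test_out_of_range_fields_rejected(self, field, value):
        with pytest.raises(ConfigError):
            SimulationConfig(**{field: value})

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_proteins=123, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestProteomeSimulation:
    def test_same_seed_gives_byte_identical_tables(self):
        cfg = SimulationConfig(n_proteins=50, n_de_proteins=5, seed=4,
                               peptides_per_condition=30, n_variants=5)
        a, b = simulate_all(cfg), simulate_all(cfg)
        assert a.matrix.to_csv() == b.matrix.to_csv()
        assert a.observations.to_csv() == b.observations.to_csv()
        assert a.variant_table.to_csv() == b.variant_table.to_csv()

    def test_planted_log2fc_recovered_within_tolerance(self):
        cfg = SimulationConfig(n_proteins=100, n_de_proteins=10, de_log2fc=2.0,
                               channel_noise_sd=0.2, peptides_per_condition=10,
                               n_variants=0, seed=7)
        matrix, truth = simulate_proteome(cfg)
        de = differential_expression(matrix)
        signed = [de.loc[acc, "log2fc"] * np.sign(true_fc)
                  for acc, true_fc in truth.de_proteins.items()]
        assert np.mean(signed) == pytest.approx(2.0, abs=0.15)

    def test_matrix_has_six_channels_and_planted_count(self):
        cfg = SimulationConfig(n_proteins=80, n_de_proteins=8, seed=1,
                               peptides_per_condition=10, n_variants=0)
        matrix, truth = simulate_proteome(cfg)
        assert matrix.shape == (80, 6)
        assert len(truth.de_proteins) == 8
        assert set(truth.de_proteins) <= set(matrix.index)


class TestImmunopeptidomeSimulation:
    def test_requires_proteome_first(self):
        cfg = SimulationConfig(n_proteins=20, n_de_proteins=0,
                               peptides_per_condition=5, n_variants=0)
        with pytest.raises(DependencyError):
            simulate_immunopeptidome(cfg, GroundTruth())

    def test_degenerate_fractions_all_coupled_in_all_18_injections(self):
        cfg = SimulationConfig(
            n_proteins=40, n_de_proteins=0, peptides_per_condition=25,
            missingness=0.0, frac_processing_shift=0.0,
            frac_protein_undetected=0.0, frac_class1_contamination=0.0,
            n_variants=0, seed=3,
        )
        study = simulate_all(cfg)
        assert set(study.truth.peptide_mode.values()) == {"expression_coupled"}
        per_pep = study.observations.groupby("sequence").size()
        assert (per_pep == 18).all()

    def test_processing_shift_fraction_recovered(self):
        cfg = SimulationConfig(
            n_proteins=150, n_de_proteins=0, peptides_per_condition=800,
            frac_processing_shift=0.1, frac_protein_undetected=0.0,
            n_variants=0, seed=5,
        )
        study = simulate_all(cfg)
        modes = pd.Series(study.truth.peptide_mode)
        frac = (modes == "processing_shifted").mean()
        # binomial tolerance: 3 SDs at n ~ 1600 draws
        assert frac == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / len(modes)))
        shifted = modes[modes == "processing_shifted"].index
        obs = study.observations[study.observations["sequence"].isin(shifted)]
        assert set(obs["condition"].unique()) == {"treated"}

    def test_truth_labels_conserved_one_per_emitted_sequence(self, small_study):
        emitted = set(small_study.observations["sequence"])
        assert set(small_study.truth.peptide_mode) == emitted
        assert small_study.truth.variant_peptides <= emitted

    def test_undetected_peptides_map_outside_the_matrix(self, small_study):
        truth = small_study.truth
        modes = pd.Series(truth.peptide_mode)
        und = modes[modes == "protein_undetected"].index
        obs = small_study.observations.set_index("sequence")
        for seq in und:
            prot = obs.loc[seq, "protein"]
            prot = prot.iloc[0] if hasattr(prot, "iloc") else prot
            assert prot in truth.hidden_proteins

    def test_class1_modal_length_is_nine(self, small_study):
        obs = small_study.observations
        class1 = obs[obs["mhc_class"] == "I"].drop_duplicates("sequence")
        lengths = class1["sequence"].str.len()
        assert lengths.value_counts().idxmax() == 9
        assert lengths.between(8, 12).all()

    def test_class2_contaminants_are_9mers_in_class2_table(self, small_study):
        truth = small_study.truth
        obs = small_study.observations
        for seq in truth.contaminant_class1:
            assert len(seq) == 9
            assert (obs.loc[obs["sequence"] == seq, "mhc_class"] == "II").all()


class TestVariantSimulation:
    def test_zero_variants_empty_outputs(self):
        cfg = SimulationConfig(n_proteins=30, n_de_proteins=0, n_variants=0,
                               peptides_per_condition=10, seed=2)
        study = simulate_all(cfg)
        assert len(study.variant_table) == 0
        assert study.truth.variant_peptides == set()

    def test_variant_sequences_differ_only_at_planted_positions(self):
        cfg = SimulationConfig(n_proteins=30, n_de_proteins=0, n_variants=10,
                               peptides_per_condition=10, seed=2)
        matrix, truth = simulate_proteome(cfg)
        table, var_seqs, truth = simulate_variants(cfg, truth)
        for acc_var, seq in var_seqs.items():
            acc = acc_var[:-4]
            wild = truth.protein_sequences[acc]
            diffs = [i + 1 for i, (a, b) in enumerate(zip(wild, seq)) if a != b]
            planted = sorted(
                int(r.pos) for r in table.itertuples() if r.protein == acc
            )
            assert diffs == planted

    def test_single_planted_substitution_round_trip(self):
        # one P->L substitution: exactly one variant protein, one diff
        wild = "MKTAPGPPPFGLSD"
        from ligandshift.variants import VariantRecord, build_variant_sequences
        out = build_variant_sequences({"TAPBP": wild},
                                      [VariantRecord("TAPBP", 5, "P", "L")])
        assert list(out) == ["TAPBP_var"]
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(wild, out["TAPBP_var"]))
                 if a != b]
        assert diffs == [(4, "P", "L")]

    def test_excessive_variant_count_rejected(self):
        cfg = SimulationConfig(n_proteins=2, n_de_proteins=0, n_variants=10,
                               protein_length_range=(20, 20),
                               peptides_per_condition=5, seed=2)
        _, truth = simulate_proteome(cfg)
        cfg2 = SimulationConfig(n_proteins=2, n_de_proteins=0, n_variants=100,
                                protein_length_range=(20, 20),
                                peptides_per_condition=5, seed=2)
        with pytest.raises(ConfigError):
            simulate_variants(cfg2, truth)

    def test_emitted_variant_peptides_carry_alt_residue(self, small_study):
        truth = small_study.truth
        obs = small_study.observations.drop_duplicates("sequence").set_index("sequence")
        by_protein = {}
        for v in truth.variant_records:
            by_protein.setdefault(v.protein_accession, []).append(v)
        assert truth.variant_peptides, "fixture should emit variant peptides"
        for seq in truth.variant_peptides:
            row = obs.loc[seq]
            hits = [v for v in by_protein.get(row["protein"], [])
                    if row["start"] <= v.position <= row["end"]
                    and seq[v.position - row["start"]] == v.alt_aa]
            assert hits


def test_aqua_panel_prefers_variant_peptides(small_study):
    cfg = small_study.config
    aqua = simulate_aqua(cfg, small_study.truth, small_study.observations)
    panel = set(aqua["peptide"])
    class1_variants = {
        s for s in small_study.truth.variant_peptides
        if (small_study.observations.loc[
            small_study.observations["sequence"] == s, "mhc_class"] == "I").all()
    }
    assert class1_variants <= panel
    assert (aqua.groupby("peptide")["bio_rep"].nunique() <= 2).all()
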