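"""Fractional ranks, the low-variance filter and the categorization table."""

import numpy as np
import pandas as pd
import pytest

from ligandshift.errors import UnmappedPeptideError
from ligandshift.categorize import (categorize_pmhc, category_summary,
                                    fractional_ranks, low_variance_filter,
                                    overlap_subcategory)

SAMPLES = [f"{c}_{r}" for c in ("control", "treated") for r in (1, 2, 3)]


def profile_frame(rows: dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=SAMPLES)
    df.index.name = "sequence"
    return df


class TestFractionalRanks:
    def test_single_peptide_gets_rank_one(self):
        ab = pd.DataFrame({"s1": [500.0]}, index=["AAAAAAAAA"])
        assert fractional_ranks(ab)["s1"].iloc[0] == 1.0

    def test_four_distinct_areas_give_quarter_steps(self):
        ab = pd.DataFrame({"s1": [40.0, 30.0, 20.0, 10.0]},
                          index=list("abcd"))
        assert fractional_ranks(ab)["s1"].tolist() == [0.25, 0.5, 0.75, 1.0]

    def test_tied_top_areas_get_average_rank(self):
        ab = pd.DataFrame({"s1": [40.0, 40.0, 20.0, 10.0]}, index=list("abcd"))
        ranks = fractional_ranks(ab)["s1"]
        assert ranks.iloc[0] == ranks.iloc[1] == pytest.approx(0.375)

    def test_most_abundant_has_lowest_rank(self, rng):
        ab = pd.DataFrame({"s1": rng.uniform(1, 1000, size=50)})
        ranks = fractional_ranks(ab)["s1"]
        assert ranks.idxmin() == ab["s1"].idxmax()

    def test_nonpositive_area_raises(self):
        with pytest.raises(Exception):
            fractional_ranks(pd.DataFrame({"s1": [-1.0]}))


class TestLowVarianceFilter:
    def test_low_spread_retained(self):
        profiles = profile_frame({"p": [0.10, 0.15, 0.20, 0.12, 0.14, 0.16]})
        assert low_variance_filter(profiles).loc["p"]

    def test_high_spread_dropped(self):
        profiles = profile_frame({"p": [0.10, 0.45, np.nan, 0.12, 0.14, 0.16]})
        assert not low_variance_filter(profiles).loc["p"]

    def test_single_replicate_only_dropped(self):
        profiles = profile_frame({"p": [0.10, np.nan, np.nan,
                                        np.nan, np.nan, np.nan]})
        assert not low_variance_filter(profiles).loc["p"]

    def test_exclusive_peptide_with_two_replicates_retained(self):
        profiles = profile_frame({"p": [np.nan, np.nan, np.nan,
                                        0.10, 0.15, np.nan]})
        assert low_variance_filter(profiles).loc["p"]


def build_inputs(peptide_rows, de_rows, detected):
    """peptide_rows: seq -> (profile 6-vector, protein, start, end)."""
    profiles = profile_frame({s: v[0] for s, v in peptide_rows.items()})
    meta = pd.DataFrame(
        {s: {"protein": v[1], "start": v[2], "end": v[3]}
         for s, v in peptide_rows.items()}
    ).T
    de = pd.DataFrame(de_rows, columns=["accession", "log2fc", "is_de"]).set_index(
        "accession"
    )
    return profiles, meta, de, set(detected)


class TestDecisionTable:
    """The 8-case truth table: peptide changed x protein detected x protein DE."""

    FLAT = [0.50, 0.52, 0.48, 0.50, 0.52, 0.48]          # unchanged profile
    SHIFT = [0.80, 0.82, 0.78, 0.30, 0.32, 0.28]         # rank delta 0.5

    @pytest.mark.parametrize(
        "pep_changed,detected,de,expected",
        [
            (False, True, False, "mirrored"),      # null case
            (False, True, True, "independent"),    # protein moved, peptide flat
            (False, False, False, "protein_unmapped"),
            (False, False, True, "protein_unmapped"),
            (True, True, False, "independent"),    # peptide moved, protein flat
            (True, True, True, "mirrored"),        # concordant change
            (True, False, False, "protein_unmapped"),
            (True, False, True, "protein_unmapped"),
        ],
    )
    def test_eight_cases_match_hand_enumerated_oracle(
        self, pep_changed, detected, de, expected
    ):
        profile = self.SHIFT if pep_changed else self.FLAT
        peptides = {"PEPTIDEAA": (profile, "P1", 10, 18)}
        de_rows = [("P1", 1.0 if de else 0.0, de)] if detected else []
        profiles, meta, de_table, det = build_inputs(
            peptides, de_rows, {"P1"} if detected else set()
        )
        out, _ = categorize_pmhc(profiles, meta, de_table, det)
        assert out.loc["PEPTIDEAA", "top_category"] == expected

    def test_discordant_directions_are_independent(self):
        # peptide up in treated (rank drops), protein DE down
        peptides = {"PEPTIDEAA": (self.SHIFT, "P1", 10, 18)}
        profiles, meta, de_table, det = build_inputs(
            peptides, [("P1", -2.0, True)], {"P1"}
        )
        out, _ = categorize_pmhc(profiles, meta, de_table, det)
        assert out.loc["PEPTIDEAA", "top_category"] == "independent"

    def test_treated_exclusive_protein_not_de_is_independent_novel(self):
        peptides = {"PEPTIDEAA": ([np.nan] * 3 + [0.2, 0.22, 0.18], "P1", 10, 18)}
        profiles, meta, de_table, det = build_inputs(
            peptides, [("P1", 0.0, False)], {"P1"}
        )
        out, _ = categorize_pmhc(profiles, meta, de_table, det)
        row = out.loc["PEPTIDEAA"]
        assert row["top_category"] == "independent"
        assert row["sub_category"] == "novel"

    def test_concordant_up_is_mirrored_abundance_shift(self):
        peptides = {"PEPTIDEAA": (self.SHIFT, "P1", 10, 18)}
        profiles, meta, de_table, det = build_inputs(
            peptides, [("P1", 1.5, True)], {"P1"}
        )
        out, _ = categorize_pmhc(profiles, meta, de_table, det)
        row = out.loc["PEPTIDEAA"]
        assert row["top_category"] == "mirrored"
        assert row["sub_category"] == "abundance_shift"

    def test_exclusive_with_overlapping_partner_is_nested_overlap(self):
        peptides = {
            "PEPTIDEAA": ([np.nan] * 3 + [0.2, 0.22, 0.18], "P1", 10, 18),
            "LONGPEPTIDECCCC": ([0.3, 0.32, 0.28, 0.3, 0.32, 0.28], "P1", 5, 19),
        }
        profiles, meta, de_table, det = build_inputs(
            peptides, [("P1", 0.0, False)], {"P1"}
        )
        out, _ = categorize_pmhc(profiles, meta, de_table, det)
        assert out.loc["PEPTIDEAA", "sub_category"] == "nested_overlap"
        assert out.loc["PEPTIDEAA", "overlap_partner"] == "LONGPEPTIDECCCC"

    def test_categories_partition_the_filtered_set(self, rng):
        peptides = {}
        for i in range(30):
            profile = rng.uniform(0.05, 0.95, size=6)
            if rng.random() < 0.3:  # some exclusives
                profile[:3] = np.nan
            peptides[f"PEP{i:03d}"] = (list(profile), f"P{i % 7}", 1, 9)
        de_rows = [(f"P{j}", 1.0, j % 2 == 0) for j in range(5)]
        profiles, meta, de_table, det = build_inputs(
            peptides, de_rows, {f"P{j}" for j in range(5)}
        )
        out, excluded = categorize_pmhc(profiles, meta, de_table, det)
        assert len(out) + len(excluded) == len(peptides)
        assert out["top_category"].isin(
            ["mirrored", "independent", "protein_unmapped"]
        ).all()
        assert not set(out.index) & set(excluded.index)

    def test_condition_swap_symmetry(self):
        peptides = {
            "PEPTIDEAA": ([np.nan] * 3 + [0.2, 0.22, 0.18], "P1", 10, 18),
            "PEPTIDECC": ([0.2, 0.22, 0.18] + [np.nan] * 3, "P2", 10, 18),
            "PEPTIDEDD": (self.SHIFT, "P3", 10, 18),
        }
        de_rows = [("P1", 0.0, False), ("P2", 0.0, False), ("P3", 0.0, False)]
        profiles, meta, de_table, det = build_inputs(
            peptides, de_rows, {"P1", "P2", "P3"}
        )
        fwd, _ = categorize_pmhc(profiles, meta, de_table, det)
        swapped = profiles[SAMPLES[3:] + SAMPLES[:3]]
        swapped.columns = SAMPLES
        rev, _ = categorize_pmhc(swapped, meta, de_table, det)
        assert fwd.loc["PEPTIDEAA", "exclusive_condition"] == "treated"
        assert rev.loc["PEPTIDEAA", "exclusive_condition"] == "control"
        assert fwd.loc["PEPTIDECC", "exclusive_condition"] == "control"
        assert rev.loc["PEPTIDECC", "exclusive_condition"] == "treated"
        assert (fwd["top_category"] == "independent").sum() == \
               (rev["top_category"] == "independent").sum()
        np.testing.assert_allclose(
            fwd["rank_delta"].astype(float), -rev["rank_delta"].astype(float)
        )

    def test_missing_protein_mapping_raises(self):
        peptides = {"PEPTIDEAA": (self.FLAT, None, 1, 9)}
        profiles, meta, de_table, det = build_inputs(peptides, [], set())
        with pytest.raises(UnmappedPeptideError):
            categorize_pmhc(profiles, meta, de_table, det)


class TestOverlapSubcategory:
    def test_nested_interval_is_nested_overlap(self):
        assert overlap_subcategory(10, 18, [(5, 20)]) == "nested_overlap"

    def test_no_partner_is_novel(self):
        assert overlap_subcategory(10, 18, []) == "novel"
        assert overlap_subcategory(10, 18, [(30, 44)]) == "novel"

    def test_matches_bruteforce_interval_intersection(self, rng):
        for _ in range(100):
            s, e = sorted(rng.integers(1, 50, size=2))
            others = [tuple(sorted(rng.integers(1, 50, size=2)))
                      for _ in range(rng.integers(0, 5))]
            expected = ("nested_overlap"
                        if any(len(set(range(s, e + 1)) & set(range(o[0], o[1] + 1))) > 0
                               for o in others) else "novel")
            assert overlap_subcategory(int(s), int(e), others) == expected


def test_category_summary_counts_and_fractions():
    assignments = pd.DataFrame({
        "top_category": ["mirrored", "mirrored", "independent"],
        "sub_category": ["unchanged", "unchanged", "novel"],
    })
    summary = category_summary(assignments)
    row = summary[summary["top_category"] == "mirrored"].iloc[0]
    assert row["count"] == 2 and row["fraction"] == pytest.approx(2 / 3)
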