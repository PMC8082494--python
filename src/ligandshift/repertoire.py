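"""Replicate filtering, exclusive repertoires and HLA locus bias.

A peptide enters a condition's repertoire only when it is identified in at
least ``min_bio`` biological replicates, each supported by at least
``min_tech`` of the technical injections (defaults 3 and 1: present in all
three biological replicates, observed in at least one injection each).
Exclusive repertoires are the set differences between conditions. Short
peptides in class-II data that score better on class-I models are flagged as
carry-over from the serial class-I immunoprecipitation. Locus bias is a
goodness-of-fit chi-squared of observed A/B/C assignment counts against
reference proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, SchemaError
from .motifs import AlleleModel, peptide_rank

OBSERVATION_COLUMNS = ["sequence", "protein", "start", "end", "condition",
                       "bio_rep", "tech_rep", "ms1_area", "mhc_class"]


@dataclass
class RepertoireSet:
    """Replicate-consistent peptides of one condition and MHC class."""

    condition: str
    mhc_class: str
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)
    # indexed by sequence; columns: protein, start, end,
    # present_rep_1..3 (bool), mean per-bio-rep areas area_rep_1..3, mean_area

    @property
    def sequences(self) -> set[str]:
        return set(self.peptides.index)


def _check_observations(obs: pd.DataFrame) -> None:
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise SchemaError(f"observation table missing columns: {missing}")


def replicate_consistent_set(
    observations: pd.DataFrame, min_bio: int = 3, min_tech: int = 1
) -> RepertoireSet:
    """Peptides observed in >= min_bio biological replicates with >= min_tech
    injections each, within a single condition x MHC class."""
    _check_observations(observations)
    conditions = observations["condition"].unique()
    classes = observations["mhc_class"].unique()
    if len(conditions) > 1 or len(classes) > 1:
        raise DataError("observations must come from one condition and one MHC class")
    condition = conditions[0] if len(conditions) else "NA"
    mhc_class = classes[0] if len(classes) else "NA"
    bio_reps = sorted(observations["bio_rep"].unique()) if len(observations) else []
    if min_bio > max(len(bio_reps), 0) and len(observations):
        raise ConfigError(
            f"min_bio={min_bio} exceeds the {len(bio_reps)} biological replicates present"
        )

    if not len(observations):
        return RepertoireSet(condition, mhc_class, pd.DataFrame())

    inj = (
        observations.groupby(["sequence", "bio_rep"])
        .agg(n_tech=("tech_rep", "nunique"), area=("ms1_area", "mean"))
        .reset_index()
    )
    supported = inj[inj["n_tech"] >= min_tech]
    n_supported = supported.groupby("sequence")["bio_rep"].nunique()
    keep = set(n_supported[n_supported >= min_bio].index)

    rows = []
    meta = observations.drop_duplicates("sequence").set_index("sequence")
    area = supported.pivot(index="sequence", columns="bio_rep", values="area")
    for seq in sorted(keep):
        entry = {
            "protein": meta.loc[seq, "protein"],
            "start": int(meta.loc[seq, "start"]),
            "end": int(meta.loc[seq, "end"]),
        }
        areas = []
        for rep in (1, 2, 3):
            a = area.loc[seq].get(rep, np.nan) if seq in area.index else np.nan
            entry[f"present_rep_{rep}"] = bool(np.isfinite(a))
            entry[f"area_rep_{rep}"] = a
            if np.isfinite(a):
                areas.append(a)
        entry["mean_area"] = float(np.mean(areas)) if areas else np.nan
        rows.append((seq, entry))
    peptides = pd.DataFrame({s: e for s, e in rows}).T
    if len(rows):
        peptides.index.name = "sequence"
        for c in ["start", "end"]:
            peptides[c] = peptides[c].astype(int)
        for rep in (1, 2, 3):
            peptides[f"present_rep_{rep}"] = peptides[f"present_rep_{rep}"].astype(bool)
            peptides[f"area_rep_{rep}"] = peptides[f"area_rep_{rep}"].astype(float)
        peptides["mean_area"] = peptides["mean_area"].astype(float)
    return RepertoireSet(condition, mhc_class, peptides)


def exclusive_sets(
    control: RepertoireSet, treated: RepertoireSet
) -> dict[str, set[str]]:
    """Partition the union of two repertoires into control-only / treated-only / shared."""
    if control.mhc_class != treated.mhc_class:
        raise DataError(
            f"MHC class mismatch: {control.mhc_class} vs {treated.mhc_class}"
        )
    c, t = control.sequences, treated.sequences
    return {"control_only": c - t, "treated_only": t - c, "shared": c & t}


def flag_class_crosscontamination(
    class2_peptides: list[str],
    class1_models: list[AlleleModel],
    class2_models: list[AlleleModel],
    max_length: int = 9,
) -> pd.DataFrame:
    """Flag short class-II peptides predicted to bind class I better than class II.

    A peptide is flagged when its length is <= ``max_length`` AND its best
    class-I percentile rank is strictly better (lower) than its best
    class-II rank — the signature of carry-over from the serial class-I
    immunoprecipitation.
    """
    if not class1_models or not class2_models:
        raise ConfigError("both class-I and class-II allele models are required")
    rows = []
    for pep in class2_peptides:
        if len(pep) > max_length:
            rows.append((pep, np.nan, np.nan, False))
            continue
        r1 = min(peptide_rank(m, pep) for m in class1_models)
        r2 = min(peptide_rank(m, pep) for m in class2_models)
        rows.append((pep, r1, r2, r1 < r2))
    return pd.DataFrame(
        rows, columns=["sequence", "best_rank_class1", "best_rank_class2", "contaminant"]
    ).set_index("sequence")


def locus_bias_test(
    exclusive_assignments: pd.Series | dict[str, str],
    reference_proportions: dict[str, float],
) -> tuple[float, float]:
    """Goodness-of-fit chi-squared of observed HLA-locus counts vs reference.

    ``exclusive_assignments`` maps peptide -> locus (e.g. 'A'/'B'/'C');
    peptides assigned to multiple loci (ties) should be pre-binned into a
    'multi' bucket and excluded by the caller. Reference proportions must
    sum to 1 over the loci considered. Returns (chi2 statistic, p-value)
    with df = loci - 1.
    """
    assignments = pd.Series(exclusive_assignments)
    total_ref = sum(reference_proportions.values())
    if not np.isclose(total_ref, 1.0):
        raise ConfigError(f"reference proportions sum to {total_ref}, expected 1")
    loci = sorted(reference_proportions)
    observed = assignments.value_counts()
    stray = set(observed.index) - set(loci)
    if stray:
        raise DataError(f"assignments contain loci without reference proportion: {stray}")
    obs = np.array([observed.get(l, 0) for l in loci], dtype=float)
    exp = np.array([reference_proportions[l] for l in loci]) * obs.sum()
    if np.any((exp == 0) & (obs > 0)):
        raise DataError("expected count 0 for an observed locus")
    nonzero = exp > 0
    chi2, p = stats.chisquare(obs[nonzero], exp[nonzero])
    return float(chi2), float(p)
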