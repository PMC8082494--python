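"""Rank-based categorization of presented peptides against the proteome.

Each quantified pMHC is placed on a fractional-rank scale within every
sample: peptides are ranked by descending MS1 area (most abundant = rank 1,
ties get the average rank) and the rank is divided by the number of
quantified peptides in that sample, giving a value in (0, 1] that is
comparable across samples of different depth. Peptides whose replicate
ranks vary by >= 0.2 within a condition, or that are seen in fewer than two
biological replicates of every condition, are set aside as too noisy to
interpret.

The remaining peptides are classified:

* ``protein_unmapped`` — the source protein was not measured in the
  parallel proteome analysis;
* ``mirrored`` — the peptide's abundance behaviour matches its protein's
  (both unchanged, or both changed in the same direction);
* ``independent`` — the peptide changed while the protein did not, changed
  in the opposite direction, or stayed flat while the protein changed —
  the signature of altered antigen processing rather than expression.

A peptide counts as *changed* when it is exclusive to one condition or its
mean fractional rank differs between conditions by >= the rank threshold
(0.2 by default, the same scale as the replicate-variance filter). A
protein counts as changed when it was called differentially expressed.
Subcategories: exclusive peptides are ``novel`` or ``nested_overlap``
(an other-condition peptide on the same protein shares positions);
non-exclusive peptides are ``abundance_shift`` or ``unchanged``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, UnmappedPeptideError

DEFAULT_RANK_THRESHOLD = 0.2

SAMPLES = [(cond, rep) for cond in ("control", "treated") for rep in (1, 2, 3)]


def sample_col(condition: str, bio_rep: int) -> str:
    return f"{condition}_{bio_rep}"


def fractional_ranks(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractional abundance ranks.

    ``abundance`` is peptides x sample columns of MS1 areas (NaN = not
    observed). Within each sample column, observed peptides are ranked by
    descending area (ties -> average rank) and divided by the number of
    observed peptides, so ranks lie in (0, 1] with the most abundant peptide
    at 1/n. Non-positive areas raise.
    """
    if (abundance <= 0).any().any():
        raise DataError("MS1 areas must be positive")
    ranks = abundance.rank(ascending=False, method="average", axis=0)
    return ranks / abundance.notna().sum(axis=0)


def condition_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean fractional rank and replicate presence per condition."""
    out = pd.DataFrame(index=profiles.index)
    for cond in ("control", "treated"):
        cols = [sample_col(cond, r) for r in (1, 2, 3) if sample_col(cond, r) in profiles]
        out[f"mean_rank_{cond}"] = profiles[cols].mean(axis=1)
        out[f"n_reps_{cond}"] = profiles[cols].notna().sum(axis=1)
    return out


def low_variance_filter(
    profiles: pd.DataFrame, threshold: float = DEFAULT_RANK_THRESHOLD
) -> pd.Series:
    """Boolean retention mask over the fractional-rank profile table.

    A peptide is retained iff (a) in every condition where it is present,
    the maximum pairwise difference of its replicate fractional ranks is
    strictly below ``threshold``, and (b) it is present in at least two
    biological replicates of at least one condition.
    """
    keep = pd.Series(True, index=profiles.index)
    any_two = pd.Series(False, index=profiles.index)
    for cond in ("control", "treated"):
        cols = [sample_col(cond, r) for r in (1, 2, 3) if sample_col(cond, r) in profiles]
        sub = profiles[cols]
        n = sub.notna().sum(axis=1)
        spread = sub.max(axis=1) - sub.min(axis=1)
        keep &= (n == 0) | (spread < threshold) | spread.isna()
        any_two |= n >= 2
    return keep & any_two


def categorize_pmhc(
    profiles: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    de_results: pd.DataFrame,
    proteome_accessions: set[str],
    rank_threshold: float = DEFAULT_RANK_THRESHOLD,
    variance_threshold: float = DEFAULT_RANK_THRESHOLD,
    contaminant_flags: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every low-variance peptide to exactly one category.

    Parameters
    ----------
    profiles:
        fractional-rank table (peptides x ``control_1`` ... ``treated_3``).
    peptide_meta:
        per-peptide ``protein, start, end`` (indexed by sequence).
    de_results:
        differential-expression table indexed by accession with
        ``log2fc`` and ``is_de``.
    proteome_accessions:
        accessions measured in the proteome analysis (detected, whether or
        not tested/DE).
    contaminant_flags:
        optional boolean Series marking likely class-I carry-over peptides;
        these are categorized but tagged.

    Returns (assignments, excluded) where ``excluded`` holds the peptides
    that failed the low-variance filter. Assignment columns:
    ``top_category, sub_category, peptide_changed, peptide_sign,
    protein_detected, protein_de, protein_sign, rank_delta,
    exclusive_condition, overlap_partner, contaminant_flag``.
    """
    unmapped = peptide_meta["protein"].isna()
    if unmapped.any():
        raise UnmappedPeptideError(
            f"{int(unmapped.sum())} peptide(s) have no protein mapping"
        )
    missing_meta = profiles.index.difference(peptide_meta.index)
    if len(missing_meta):
        raise UnmappedPeptideError(
            f"{len(missing_meta)} peptide(s) missing from the metadata table"
        )
    if not 0 < rank_threshold <= 1:
        raise ConfigError("rank_threshold must lie in (0, 1]")

    keep = low_variance_filter(profiles, variance_threshold)
    retained, excluded = profiles[keep], profiles[~keep]
    summary = condition_summary(retained)

    # positional index of other-condition peptides per protein, for overlap
    meta = peptide_meta.loc[retained.index]
    by_protein: dict[str, list[tuple[str, int, int, str]]] = {}
    for seq, m in meta.iterrows():
        ex = _exclusivity(summary.loc[seq])
        by_protein.setdefault(m["protein"], []).append((seq, int(m["start"]), int(m["end"]), ex))

    rows = []
    for seq in retained.index:
        s = summary.loc[seq]
        protein = meta.loc[seq, "protein"]
        exclusive = _exclusivity(s)
        rank_delta = (
            s["mean_rank_control"] - s["mean_rank_treated"]
            if s["n_reps_control"] > 0 and s["n_reps_treated"] > 0
            else np.nan
        )  # positive = more abundant (lower rank) in treated
        peptide_changed = exclusive is not None or (
            np.isfinite(rank_delta) and abs(rank_delta) >= rank_threshold
        )
        if exclusive == "treated":
            peptide_sign = 1
        elif exclusive == "control":
            peptide_sign = -1
        elif peptide_changed:
            peptide_sign = int(np.sign(rank_delta))
        else:
            peptide_sign = 0

        detected = protein in proteome_accessions
        in_de_table = protein in de_results.index
        protein_de = bool(de_results.loc[protein, "is_de"]) if in_de_table else False
        protein_sign = (
            int(np.sign(de_results.loc[protein, "log2fc"])) if protein_de else 0
        )

        if not detected:
            top = "protein_unmapped"
        elif peptide_changed == protein_de and (
            not peptide_changed or peptide_sign == protein_sign
        ):
            top = "mirrored"
        else:
            top = "independent"

        partner = None
        if exclusive is not None:
            other = "control" if exclusive == "treated" else "treated"
            ps, pe = int(meta.loc[seq, "start"]), int(meta.loc[seq, "end"])
            for oseq, os_, oe, oex in by_protein.get(protein, []):
                if oseq == seq or oex == exclusive:
                    continue  # partner must be present in the other condition
                if oex in (None, other) and os_ <= pe and ps <= oe:
                    partner = oseq
                    break
            sub = "nested_overlap" if partner else "novel"
        else:
            sub = "abundance_shift" if peptide_changed else "unchanged"

        rows.append({
            "sequence": seq,
            "top_category": top,
            "sub_category": sub,
            "peptide_changed": peptide_changed,
            "peptide_sign": peptide_sign,
            "protein_detected": detected,
            "protein_de": protein_de,
            "protein_sign": protein_sign,
            "rank_delta": rank_delta,
            "exclusive_condition": exclusive or "",
            "overlap_partner": partner or "",
            "contaminant_flag": bool(contaminant_flags.get(seq, False))
            if contaminant_flags is not None else False,
        })
    assignments = pd.DataFrame(rows).set_index("sequence") if rows else pd.DataFrame(
        columns=["top_category", "sub_category"]
    )
    return assignments, excluded


def overlap_subcategory(
    start: int, end: int, other_condition_intervals: list[tuple[int, int]]
) -> str:
    """Subcategory of a condition-exclusive peptide given same-protein
    peptides present in the other condition: ``nested_overlap`` when any
    shares at least one position (1-based inclusive intervals), else
    ``novel``."""
    for os_, oe in other_condition_intervals:
        if os_ <= end and start <= oe:
            return "nested_overlap"
    return "novel"


def _exclusivity(summary_row: pd.Series) -> str | None:
    """'control'/'treated' if present in exactly one condition, else None."""
    c, t = summary_row["n_reps_control"], summary_row["n_reps_treated"]
    if c > 0 and t == 0:
        return "control"
    if t > 0 and c == 0:
        return "treated"
    return None


def category_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per (top_category, sub_category)."""
    counts = (
        assignments.groupby(["top_category", "sub_category"])
        .size()
        .rename("count")
        .reset_index()
    )
    counts["fraction"] = counts["count"] / max(len(assignments), 1)
    return counts
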