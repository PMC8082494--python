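"""Core-epitope consolidation, imputation and differential presentation.

Overlapping/nested replicate-consistent peptides on one protein are
consolidated into *core epitopes*: connected components of the interval
overlap graph whose core is the intersection of member intervals, provided
that intersection is at least ``min_epitope_length`` residues. Components
with an empty or too-short intersection are split greedily at the position
of minimal peptide coverage (leftmost tie-break; positions whose split makes
no progress are passed over) and re-processed; components that cannot be
split are logged as unresolvable. The consolidated abundance of a core is
the SUM of its member peptides' MS1 areas per sample, so total area is
conserved between input peptides and (cores + unresolvable) output.

Missing per-sample core abundances are imputed with the lowest measured
value of that sample column. Differential presentation is a two-sample
t-test on log2 consolidated abundances with Benjamini-Hochberg correction;
both raw-p and adjusted calls are reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigError, CoordinateError, ImputationError,
                     InsufficientReplicatesError)
from .proteome import _group_test, benjamini_hochberg

logger = logging.getLogger(__name__)

DEFAULT_MIN_EPITOPE_LENGTH_I = 9
#: class II is consolidated at both minimum lengths, outputs kept side by side
MIN_EPITOPE_LENGTHS_II = (9, 13)


def _connected_components(intervals: list[tuple[int, int]]) -> list[list[int]]:
    """Indices grouped into connected components of the overlap graph
    (1-based inclusive intervals; overlap = sharing >= 1 position)."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    comps, current, reach = [], [], -1
    for i in order:
        s, e = intervals[i]
        if current and s > reach:
            comps.append(current)
            current = []
        current.append(i)
        reach = max(reach, e)
    if current:
        comps.append(current)
    return comps


def _resolve_component(
    peps: pd.DataFrame, min_len: int, cores: list, unresolved: list
) -> None:
    intervals = list(zip(peps["start"], peps["end"]))
    for comp in _connected_components(intervals):
        sub = peps.iloc[comp]
        core_start = int(sub["start"].max())
        core_end = int(sub["end"].min())
        if core_end - core_start + 1 >= min_len:
            cores.append((sub, core_start, core_end))
            continue
        lo, hi = int(sub["start"].min()), int(sub["end"].max())
        positions = np.arange(lo, hi + 1)
        coverage = np.zeros(positions.size, dtype=int)
        for s, e in zip(sub["start"], sub["end"]):
            coverage[s - lo : e - lo + 1] += 1
        # candidate split positions in (coverage, position) order; take the
        # first that actually separates the component
        for p in positions[np.lexsort((positions, coverage))]:
            left_mask = []
            for s, e in zip(sub["start"], sub["end"]):
                if e < p:
                    left_mask.append(True)
                elif s > p:
                    left_mask.append(False)
                else:  # peptide covers p: side with the larger overlap, ties left
                    left_mask.append((p - s) >= (e - p))
            left_mask = np.array(left_mask)
            if 0 < left_mask.sum() < len(sub):
                _resolve_component(sub[left_mask], min_len, cores, unresolved)
                _resolve_component(sub[~left_mask], min_len, cores, unresolved)
                break
        else:
            unresolved.append(sub)


def infer_core_epitopes(
    peptides: pd.DataFrame,
    min_epitope_length: int = DEFAULT_MIN_EPITOPE_LENGTH_I,
    sample_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consolidate quantified peptides into core epitopes.

    ``peptides`` needs ``sequence, protein, start, end`` plus per-sample
    abundance columns (``sample_cols``; by default every numeric column not
    among the coordinates). Returns ``(cores, unresolved)``; consolidated
    abundances are per-sample sums over members (NaN-aware).
    """
    required = {"sequence", "protein", "start", "end"}
    if not required.issubset(peptides.columns):
        raise ConfigError(f"peptide table must have columns {sorted(required)}")
    bad = peptides["end"] - peptides["start"] + 1 != peptides["sequence"].str.len()
    if bad.any():
        raise CoordinateError(
            f"{int(bad.sum())} peptide(s) with interval inconsistent with sequence length"
        )
    if sample_cols is None:
        sample_cols = [
            c for c in peptides.columns
            if c not in required and pd.api.types.is_numeric_dtype(peptides[c])
        ]

    core_rows, unresolved_parts = [], []
    for protein, group in peptides.groupby("protein", sort=True):
        found: list = []
        _resolve_component(group, min_epitope_length, found, unresolved_parts)
        for sub, cs, ce in found:
            anchor = sub.iloc[0]
            core_seq = anchor["sequence"][cs - anchor["start"]: ce - anchor["start"] + 1]
            row = {
                "protein": protein,
                "core_start": cs,
                "core_end": ce,
                "core_sequence": core_seq,
                "members": ";".join(sorted(sub["sequence"])),
                "n_members": len(sub),
            }
            for c in sample_cols:
                row[c] = sub[c].sum(min_count=1)
            core_rows.append(row)
    cores = pd.DataFrame(core_rows)
    unresolved = (
        pd.concat(unresolved_parts) if unresolved_parts
        else peptides.iloc[0:0]
    )
    if len(unresolved):
        logger.info("core inference: %d peptide(s) unresolvable", len(unresolved))
    return cores, unresolved


def impute_missing(
    core_matrix: pd.DataFrame, sample_cols: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill each missing cell with the lowest measured value of its sample column.

    Returns (completed matrix, boolean mask of imputed cells). A sample
    column with no measured value at all cannot be imputed and raises.
    """
    out = core_matrix.copy()
    mask = pd.DataFrame(False, index=core_matrix.index, columns=sample_cols)
    for c in sample_cols:
        col = out[c]
        if col.notna().sum() == 0:
            raise ImputationError(f"sample column {c!r} has no measured value")
        mask[c] = col.isna()
        out[c] = col.fillna(col.min())
    return out, mask


def differential_presentation(
    core_matrix: pd.DataFrame,
    control_cols: list[str],
    treated_cols: list[str],
    p_thresh: float = 0.05,
    log2fc_thresh: float = 1.0,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test on log2 consolidated abundances per core.

    ``direction`` uses the raw p-value with the |log2fc| threshold
    (up_treated / up_control / unchanged); ``direction_adjusted`` applies
    the same rule with the Benjamini-Hochberg q-value.
    """
    if len(control_cols) < 2 or len(treated_cols) < 2:
        raise InsufficientReplicatesError("need >=2 samples per condition")
    sub = core_matrix[control_cols + treated_cols]
    if sub.isna().any().any():
        raise InsufficientReplicatesError(
            "missing abundances present; run impute_missing first"
        )
    log2 = np.log2(sub.astype(float))
    lfc = log2[treated_cols].mean(axis=1) - log2[control_cols].mean(axis=1)
    pvals = np.array([
        _group_test(row[control_cols].to_numpy(float), row[treated_cols].to_numpy(float), welch)
        for _, row in log2.iterrows()
    ])
    out = core_matrix.copy()
    out["log2fc"] = lfc
    out["p_value"] = pvals
    out["q_value"] = benjamini_hochberg(pvals)

    def call(p: pd.Series) -> pd.Series:
        changed = (p < p_thresh) & (lfc.abs() > log2fc_thresh)
        d = pd.Series("unchanged", index=out.index)
        d[changed & (lfc > 0)] = "up_treated"
        d[changed & (lfc < 0)] = "up_control"
        return d

    out["direction"] = call(out["p_value"])
    out["direction_adjusted"] = call(out["q_value"])
    return out
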