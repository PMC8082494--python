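"""Targeted quantification of SNP/neoantigen peptides against heavy standards.

Each endogenous (light) peptide is quantified relative to its isotopically
labelled (heavy) standard spiked at a known amount:
``amount = light_area / heavy_area * spike_amount`` (fmol). For
differential testing, technical injections are averaged per biological
replicate, the biological-replicate means are compared by a two-sample
t-test (the panel design has n=2 per condition — a low-power setting, which
is warned about), q-values are Benjamini-Hochberg over the peptide panel,
and per-peptide z-scores standardize the 2+2 per-condition means
(population convention: they sum to 0 with unit variance). A peptide is
called significant when p < 0.05 and q < 0.49.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, SchemaError, StandardNotDetectedError
from .proteome import _group_test, benjamini_hochberg

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["peptide", "condition", "bio_rep", "tech_rep",
                       "light_area", "heavy_area", "spike_amount"]

P_THRESH = 0.05
Q_THRESH = 0.49


def quantify_against_standard(
    light_area: float, heavy_area: float, spike_amount: float
) -> float:
    """Endogenous amount in fmol from the light/heavy MS1 area ratio."""
    if not heavy_area > 0:
        raise StandardNotDetectedError(
            f"heavy standard area must be positive, got {heavy_area}"
        )
    if not spike_amount > 0:
        raise StandardNotDetectedError(
            f"spike amount must be positive, got {spike_amount}"
        )
    return light_area / heavy_area * spike_amount


def quantify_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`quantify_against_standard`; adds ``amount_fmol``."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    if (measurements["heavy_area"] <= 0).any():
        raise StandardNotDetectedError("non-positive heavy-standard area present")
    out = measurements.copy()
    out["amount_fmol"] = (
        out["light_area"] / out["heavy_area"] * out["spike_amount"]
    )
    return out


def differential_targets(
    measurements: pd.DataFrame,
    p_thresh: float = P_THRESH,
    q_thresh: float = Q_THRESH,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-peptide differential presentation from AQUA amounts.

    Returns a DataFrame indexed by peptide with the per-replicate mean
    amounts (``control_1, control_2, treated_1, treated_2``...), ``log2fc``
    of condition means, ``p_value``, ``q_value``, per-mean z-scores
    (``z_<condition>_<rep>``), ``direction`` and ``significant``. The
    default is Student's pooled-variance t-test: with two biological
    replicates per condition the Welch degrees-of-freedom estimate is
    unstable.
    """
    quant = quantify_table(measurements)
    rep_means = (
        quant.groupby(["peptide", "condition", "bio_rep"])["amount_fmol"]
        .mean()
        .reset_index()
    )
    rows = []
    for pep, grp in rep_means.groupby("peptide"):
        by_cond = {
            cond: sub.sort_values("bio_rep")
            for cond, sub in grp.groupby("condition")
        }
        for cond in ("control", "treated"):
            if cond not in by_cond or len(by_cond[cond]) < 2:
                raise InsufficientReplicatesError(
                    f"peptide {pep}: condition {cond!r} has <2 biological replicates"
                )
        ctrl = by_cond["control"]["amount_fmol"].to_numpy(float)
        trt = by_cond["treated"]["amount_fmol"].to_numpy(float)
        p = _group_test(ctrl, trt, welch)
        means = np.concatenate([ctrl, trt])
        sd = means.std(ddof=0)
        z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        with np.errstate(divide="ignore"):
            lfc = float(np.log2(trt.mean()) - np.log2(ctrl.mean())) \
                if ctrl.mean() > 0 and trt.mean() > 0 else np.nan
        row = {"peptide": pep, "log2fc": lfc, "p_value": p}
        labels = [f"control_{r}" for r in by_cond["control"]["bio_rep"]] + \
                 [f"treated_{r}" for r in by_cond["treated"]["bio_rep"]]
        for lab, m, zz in zip(labels, means, z):
            row[lab] = m
            row[f"z_{lab}"] = zz
        rows.append(row)
    out = pd.DataFrame(rows).set_index("peptide")
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = (out["p_value"] < p_thresh) & (out["q_value"] < q_thresh)
    out["direction"] = np.where(
        ~out["significant"], "unchanged",
        np.where(out["log2fc"] > 0, "up_treated", "down_treated"),
    )
    n_rep = rep_means.groupby(["peptide", "condition"])["bio_rep"].nunique().min()
    if n_rep <= 2:
        logger.warning(
            "AQUA panel tested with %d biological replicates per condition: "
            "low statistical power", int(n_rep),
        )
    return out.sort_values("q_value")
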