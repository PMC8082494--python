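"""TMT reporter-channel differential protein expression.

Six reporter channels (three control, three treated), log2-transformed,
compared with an unpaired two-sample t-test (Welch by default), with
Benjamini-Hochberg correction across all tested proteins. A protein is
called differentially expressed when p < 0.01 and its linear fold-change
is at least 1.2 (i.e. |log2 fold-change| >= log2 1.2); both thresholds are
parameters. Quantified rows must carry a signal in at least four of the six
channels to be tested at all.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, SchemaError

logger = logging.getLogger(__name__)

CONTROL_CHANNELS = ["tmt126", "tmt127n", "tmt128c"]
TREATED_CHANNELS = ["tmt129n", "tmt130c", "tmt131"]
ALL_CHANNELS = CONTROL_CHANNELS + TREATED_CHANNELS

DEFAULT_P_THRESH = 0.01
DEFAULT_FC_THRESH = 1.2  # linear fold-change


def filter_quant_peptides(
    table: pd.DataFrame, channel_cols: list[str] | None = None, min_observed: int = 4
) -> pd.DataFrame:
    """Keep rows observed (non-missing, positive) in >= ``min_observed`` channels."""
    cols = channel_cols or ALL_CHANNELS
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"missing channel columns: {missing}")
    observed = table[cols].gt(0).fillna(False).sum(axis=1)
    kept = table[observed >= min_observed]
    logger.info("channel filter: kept %d / %d rows (>=%d of %d channels)",
                len(kept), len(table), min_observed, len(cols))
    return kept


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _group_test(x: np.ndarray, y: np.ndarray, welch: bool) -> float:
    """Two-sample t-test p on log2 values; zero-variance-equal-means -> p=1."""
    if np.allclose(x.var(ddof=0), 0) and np.allclose(y.var(ddof=0), 0):
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    p = stats.ttest_ind(x, y, equal_var=not welch).pvalue
    return 1.0 if np.isnan(p) else float(p)


def differential_expression(
    matrix: pd.DataFrame,
    control_cols: list[str] | None = None,
    treated_cols: list[str] | None = None,
    p_thresh: float = DEFAULT_P_THRESH,
    fc_thresh: float = DEFAULT_FC_THRESH,
    welch: bool = True,
) -> pd.DataFrame:
    """Per-protein differential expression between channel groups.

    ``matrix`` is indexed by accession with positive (or NaN) channel
    intensities. Group statistics use observed values only; proteins with
    fewer than two observations in either group are excluded (and counted in
    the log). ``log2fc`` is mean(log2 treated) - mean(log2 control).

    Returns a DataFrame indexed by accession with columns
    ``log2fc, p_value, q_value, is_de``.
    """
    ctrl = control_cols or CONTROL_CHANNELS
    trt = treated_cols or TREATED_CHANNELS
    missing = [c for c in ctrl + trt if c not in matrix.columns]
    if missing:
        raise SchemaError(f"missing channel columns: {missing}")
    if fc_thresh < 1:
        raise ConfigError("fold-change threshold must be >= 1 (linear scale)")
    if (matrix[ctrl + trt] <= 0).any().any():
        raise DataError("non-positive intensity encountered; cannot log-transform")

    log2 = np.log2(matrix[ctrl + trt])
    results, excluded = [], 0
    for acc, row in log2.iterrows():
        x = row[ctrl].dropna().to_numpy(dtype=float)
        y = row[trt].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            excluded += 1
            continue
        results.append((acc, float(y.mean() - x.mean()), _group_test(x, y, welch)))
    if excluded:
        logger.info("differential expression: excluded %d protein(s) with <2 "
                    "observations per group", excluded)
    if not results:
        return pd.DataFrame(columns=["log2fc", "p_value", "q_value", "is_de"])
    out = pd.DataFrame(results, columns=["accession", "log2fc", "p_value"]).set_index("accession")
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    lfc_thresh = np.log2(fc_thresh)
    out["is_de"] = (out["p_value"] < p_thresh) & (out["log2fc"].abs() >= lfc_thresh)
    logger.info("differential expression: %d / %d proteins called DE "
                "(p<%g, fold>=%g)", int(out["is_de"].sum()), len(out), p_thresh, fc_thresh)
    return out
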