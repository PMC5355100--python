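"""Normalization and paired differential expression.

The stage mirrors a standard two-color-array workflow: quantile
normalization across samples, per-probe log2 fold change over matched
tumor/normal pairs, a two-tailed Student t-test on log2 intensities,
Benjamini-Hochberg adjustment, and volcano filtering at fold change
> 2.0 with FDR < 0.05 (both strict).

Fold change is computed as the mean of per-pair log2 ratios
(mean-of-ratios), which respects the paired design; ratio-of-means is
available as an alternative estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .matrix import paired_design, validate_matrix

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NO_DIRECTION = "none"

DE_COLUMNS = ("log2fc", "p_raw", "fdr", "direction", "passes_filter")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common mean quantile profile.

    Each column's sorted values are replaced by the row-wise mean of all
    sorted columns; within-column rank order is preserved. Tied values
    within a column receive the mean of the reference values they span,
    so the map is well defined and deterministic.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputError("cannot quantile-normalize an empty matrix")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average the reference values assigned to tied input values
        ties = pd.Series(mapped).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = ties.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def paired_log2fc(
    matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    estimator: str = "mean_of_ratios",
) -> pd.Series:
    """Per-probe tumor-vs-normal log2 fold change over matched pairs.

    ``mean_of_ratios`` (default) averages log2((T_i+c)/(N_i+c)) over
    pairs; ``ratio_of_means`` takes log2 of the ratio of group means.
    """
    design = validate_matrix(matrix)
    tumor = matrix.loc[:, list(design.tumor_cols)].to_numpy(dtype=float)
    normal = matrix.loc[:, list(design.normal_cols)].to_numpy(dtype=float)
    if estimator == "mean_of_ratios":
        lfc = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
        result = lfc.mean(axis=1)
    elif estimator == "ratio_of_means":
        result = np.log2(tumor.mean(axis=1) + pseudocount) - np.log2(
            normal.mean(axis=1) + pseudocount
        )
    else:
        raise InputError(f"unknown fold-change estimator {estimator!r}")
    return pd.Series(result, index=matrix.index, name="log2fc")


def t_test(matrix: pd.DataFrame, mode: str = "two_sample") -> pd.Series:
    """Two-tailed Student t-test per probe on log2(intensity + 1).

    ``two_sample`` pools tumor vs normal with the classic equal-variance
    statistic; ``paired`` tests the per-pair log2 differences. Probes
    with zero variance everywhere are degenerate and are assigned p = 1
    with a logged warning, keeping the pipeline total.
    """
    design = validate_matrix(matrix)
    if design.n_pairs < 2:
        raise InputError("t-test needs at least 2 pairs")
    log_t = np.log2(matrix.loc[:, list(design.tumor_cols)].to_numpy(float) + 1.0)
    log_n = np.log2(matrix.loc[:, list(design.normal_cols)].to_numpy(float) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "paired":
            diff = log_t - log_n
            degenerate = diff.std(axis=1, ddof=1) == 0
            p = stats.ttest_rel(log_t, log_n, axis=1).pvalue
        elif mode == "two_sample":
            degenerate = (
                log_t.var(axis=1, ddof=1) + log_n.var(axis=1, ddof=1)
            ) == 0
            p = stats.ttest_ind(log_t, log_n, axis=1, equal_var=True).pvalue
        else:
            raise InputError(f"unknown t-test mode {mode!r}")
    p = np.asarray(p, dtype=float)
    bad = degenerate | ~np.isfinite(p)
    if bad.any():
        logger.warning(
            "%d probe(s) with zero-variance (degenerate) t-test; p set to 1", bad.sum()
        )
        p[bad] = 1.0
    return pd.Series(p, index=matrix.index, name="p_raw")


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (classic FDR control).

    Order-preserving; ties share an adjusted value; clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_filter(
    de: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> tuple[list, list]:
    """Partition probes passing the volcano criteria into up/down lists.

    A probe passes when its fold change 2^|log2fc| strictly exceeds
    ``fc_threshold`` and its FDR is strictly below ``fdr_threshold``.
    An ``fdr_threshold`` >= 1 disables the FDR gate (adjusted values of
    exactly 1.0 are common and a strict test would exclude them even
    when the caller wants the filter off).
    """
    lfc = de["log2fc"].to_numpy(dtype=float)
    fdr = de["fdr"].to_numpy(dtype=float)
    passes = np.exp2(np.abs(lfc)) > fc_threshold
    if fdr_threshold < 1:
        passes &= fdr < fdr_threshold
    up = de.index[passes & (lfc > 0)].tolist()
    down = de.index[passes & (lfc < 0)].tolist()
    return up, down


def de_table(
    matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    test_mode: str = "two_sample",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    estimator: str = "mean_of_ratios",
    probe_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Full DE result per probe: log2fc, p_raw, fdr, direction, flag.

    When ``probe_classes`` is given (e.g. lncRNA vs mRNA), BH adjustment
    is applied within each class separately, matching workflows that
    report the two universes as separate experiments; otherwise jointly.
    """
    lfc = paired_log2fc(matrix, pseudocount=pseudocount, estimator=estimator)
    p_raw = t_test(matrix, mode=test_mode)
    fdr = pd.Series(np.ones(len(p_raw)), index=p_raw.index, name="fdr")
    if probe_classes is not None:
        classes = probe_classes.reindex(p_raw.index)
        if classes.isna().any():
            missing = classes.index[classes.isna()].tolist()
            raise InputError(f"probes without a class label: {missing[:5]}")
        for cls in classes.unique():
            mask = (classes == cls).to_numpy()
            fdr.iloc[mask] = benjamini_hochberg(p_raw.iloc[mask].to_numpy())
    else:
        fdr[:] = benjamini_hochberg(p_raw.to_numpy())
    table = pd.DataFrame({"log2fc": lfc, "p_raw": p_raw, "fdr": fdr})
    up, down = volcano_filter(table, fc_threshold, fdr_threshold)
    table["direction"] = NO_DIRECTION
    table.loc[up, "direction"] = UP
    table.loc[down, "direction"] = DOWN
    table["passes_filter"] = table["direction"] != NO_DIRECTION
    logger.info(
        "DE filter: %d/%d probes pass (%d up, %d down)",
        table["passes_filter"].sum(), len(table), len(up), len(down),
    )
    return table


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"DE table missing columns: {missing}")
    return df


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="probe_id")
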