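"""Relative qPCR quantification by the 2^-ddCp method.

Replicate crossing points (Cp; one cycle = one doubling of template)
are averaged per (sample, gene) on the Cp scale, referenced to a stable
housekeeping gene in the same sample (dCp = Cp_target - Cp_reference),
and calibrated against a control (ddCp = dCp_sample - dCp_calibrator).
Relative expression is 2^-ddCp, assuming perfect amplification
efficiency of 2 as the method's name implies.

Two calibrators are supported: the matched adjacent-normal sample of the
same pair (``paired_normal``, natural for a paired design), or the mean
dCp over all normal samples per gene (``group_mean_normal``, which keeps
normal-sample values informative for group-level ROC analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import NORMAL, sample_group, sample_pair

CP_COLUMNS = ("sample", "group", "gene", "replicate", "cp")

PAIRED_NORMAL = "paired_normal"
GROUP_MEAN_NORMAL = "group_mean_normal"


def read_cp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CP_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"Cp table missing columns: {missing}")
    return df


def write_cp_table(table: pd.DataFrame, path) -> None:
    table.loc[:, list(CP_COLUMNS)].to_csv(path, index=False)


def collapse_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean Cp per (sample, gene), with replicate SD and count for QC.

    Every sample must carry every gene; missing combinations are
    reported as an error so a truncated plate is caught early.
    """
    df = measurements
    missing_cols = [c for c in ("sample", "gene", "cp") if c not in df.columns]
    if missing_cols:
        raise InputError(f"Cp table missing columns: {missing_cols}")
    cp = df["cp"].to_numpy(dtype=float)
    if not np.isfinite(cp).all() or (cp <= 0).any():
        raise InputError("Cp values must be positive and finite")
    grouped = df.groupby(["sample", "gene"], sort=False)["cp"]
    out = grouped.agg(mean_cp="mean", sd_cp="std", n_replicates="count").reset_index()
    out["sd_cp"] = out["sd_cp"].fillna(0.0)  # single replicate: SD undefined -> 0
    if "group" in df.columns:
        groups = df.drop_duplicates("sample").set_index("sample")["group"]
        out.insert(1, "group", out["sample"].map(groups).to_numpy())
    samples, genes = out["sample"].unique(), out["gene"].unique()
    have = set(zip(out["sample"], out["gene"]))
    gaps = [(s, g) for s in samples for g in genes if (s, g) not in have]
    if gaps:
        raise InputError(f"missing (sample, gene) Cp measurements: {gaps[:10]}")
    return out


def ddcp(
    mean_cp: pd.DataFrame,
    reference_gene: str,
    calibrator: str = PAIRED_NORMAL,
) -> pd.DataFrame:
    """Reference-normalized, calibrated relative expression per sample.

    ``mean_cp`` is the collapsed table (sample, [group,] gene, mean_cp).
    Sample names follow the ``<pair>_T/<pair>_N`` convention, which
    supplies the pairing for the ``paired_normal`` calibrator. Returns a
    tidy table with delta_cp, ddcp and rel_expr = 2^-ddcp per
    (sample, target gene); the reference gene itself is not reported.
    """
    if calibrator not in (PAIRED_NORMAL, GROUP_MEAN_NORMAL):
        raise InputError(f"unknown calibrator {calibrator!r}")
    wide = mean_cp.pivot(index="sample", columns="gene", values="mean_cp")
    if reference_gene not in wide.columns:
        raise InputError(f"reference gene {reference_gene!r} not measured")
    ref = wide[reference_gene]
    if ref.isna().any():
        missing = wide.index[ref.isna()].tolist()
        raise InputError(f"reference gene missing for sample(s): {missing}")
    targets = [g for g in wide.columns if g != reference_gene]
    dcp = wide[targets].sub(ref, axis=0)

    groups = pd.Series(
        ["tumor" if sample_group(s) != NORMAL else "normal" for s in dcp.index],
        index=dcp.index,
    )
    if calibrator == PAIRED_NORMAL:
        normal_by_pair = {
            sample_pair(s): s for s in dcp.index if sample_group(s) == NORMAL
        }
        cal_rows = []
        for s in dcp.index:
            pair = sample_pair(s)
            if pair not in normal_by_pair:
                raise InputError(f"no paired normal sample for {s!r}")
            cal_rows.append(dcp.loc[normal_by_pair[pair]])
        cal = pd.DataFrame(cal_rows, index=dcp.index)
    else:
        normals = dcp.loc[[s for s in dcp.index if sample_group(s) == NORMAL]]
        if normals.empty:
            raise InputError("group_mean_normal calibrator needs normal samples")
        cal = pd.DataFrame(
            np.tile(normals.mean(axis=0).to_numpy(), (len(dcp), 1)),
            index=dcp.index, columns=dcp.columns,
        )
    dd = dcp - cal
    out = (
        dd.stack()
        .rename("ddcp")
        .reset_index()
        .rename(columns={"level_1": "gene"})
    )
    out.insert(1, "group", out["sample"].map(groups).to_numpy())
    out["delta_cp"] = dcp.stack().to_numpy()
    out["rel_expr"] = np.exp2(-out["ddcp"])
    return out[["sample", "group", "gene", "delta_cp", "ddcp", "rel_expr"]]


def relative_expression(
    measurements: pd.DataFrame,
    reference_gene: str = "ACTB",
    calibrator: str = PAIRED_NORMAL,
) -> pd.DataFrame:
    """Convenience: collapse replicates then apply the 2^-ddCp method."""
    return ddcp(
        collapse_replicates(measurements), reference_gene, calibrator=calibrator
    )
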