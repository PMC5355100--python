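"""Candidate-biomarker selection on raw probe intensities.

A differentially expressed lncRNA is promoted to candidate biomarker
when it is measured reliably and its between-group signal dwarfs the
within-group spread of at least one group. Concretely, with raw (never
normalized, never logged) intensities:

* T-bar, N-bar — mean raw intensity over tumor / normal samples;
* A = |T-bar - N-bar| — the between-group separation;
* t_range, n_range — max minus min raw intensity within each group;
* intensity gate — every sample of the probe lies in [100, 20,000]
  (inclusive by default; the bounds are configurable);
* selection — the probe is on the DE list, passes the gate, and at
  least one group's range is strictly smaller than A/10 (an AND mode
  requiring both groups is available).

The statistic is deliberately scale-free apart from the gate:
multiplying a probe's intensities by a constant scales A and both
ranges together, leaving selection unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DOWN, UP
from .errors import InputError
from .matrix import validate_matrix

logger = logging.getLogger(__name__)

GATE_LOW, GATE_HIGH = 100.0, 20_000.0

STATS_COLUMNS = (
    "probe_id", "t_bar", "n_bar", "a", "t_range", "n_range",
    "in_gate", "selected", "direction",
)


@dataclass(frozen=True)
class CandidateStats:
    """Selection-statistic bundle for one probe."""

    probe_id: str
    t_bar: float
    n_bar: float
    a: float
    t_range: float
    n_range: float
    in_gate: bool
    selected: bool
    direction: str


def candidate_stats(
    probe_id: str,
    tumor,
    normal,
    gate: tuple[float, float] | None = (GATE_LOW, GATE_HIGH),
    ratio: float = 10.0,
    require_both_stable: bool = False,
) -> CandidateStats:
    """Compute the selection statistic for one probe's raw intensities.

    ``gate=None`` disables the intensity gate (useful when studying the
    scale-free part of the rule). The range test is strict: a range
    exactly equal to A/``ratio`` does not select.
    """
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(normal, dtype=float)
    if t.size < 1 or n.size < 1 or t.size != n.size:
        raise InputError(f"probe {probe_id!r}: need equal, non-empty groups")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise InputError(f"probe {probe_id!r}: missing or non-finite intensity")
    if ratio <= 0:
        raise InputError("ratio must be positive")
    t_bar, n_bar = float(t.mean()), float(n.mean())
    a = abs(t_bar - n_bar)
    t_range = float(t.max() - t.min())
    n_range = float(n.max() - n.min())
    if gate is None:
        in_gate = True
    else:
        low, high = gate
        values = np.concatenate([t, n])
        in_gate = bool(((values >= low) & (values <= high)).all())
    stable_t, stable_n = t_range < a / ratio, n_range < a / ratio
    stable = (stable_t and stable_n) if require_both_stable else (stable_t or stable_n)
    return CandidateStats(
        probe_id=probe_id, t_bar=t_bar, n_bar=n_bar, a=a,
        t_range=t_range, n_range=n_range, in_gate=in_gate,
        selected=bool(in_gate and stable),
        direction=UP if t_bar >= n_bar else DOWN,
    )


def select_candidates(
    matrix: pd.DataFrame,
    de_list,
    gate: tuple[float, float] | None = (GATE_LOW, GATE_HIGH),
    ratio: float = 10.0,
    require_both_stable: bool = False,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Apply the selection statistic to every DE probe of a raw matrix.

    Returns (up candidates, down candidates, full stats table) with the
    table ordered by descending A (ties by probe id) so the strongest
    separations rank first. Probes with missing values are excluded with
    a warning; a DE probe absent from the matrix is an error.
    """
    design = validate_matrix(matrix)
    de_list = list(de_list)
    absent = [p for p in de_list if p not in matrix.index]
    if absent:
        raise InputError(f"DE probes missing from the matrix: {absent}")
    tumor = matrix.loc[:, list(design.tumor_cols)]
    normal = matrix.loc[:, list(design.normal_cols)]
    rows, skipped = [], []
    for probe in de_list:
        try:
            stats = candidate_stats(
                probe, tumor.loc[probe].to_numpy(), normal.loc[probe].to_numpy(),
                gate=gate, ratio=ratio, require_both_stable=require_both_stable,
            )
        except InputError:
            skipped.append(probe)
            continue
        rows.append(stats.__dict__)
    if skipped:
        logger.warning("excluded %d unevaluable probe(s): %s", len(skipped), skipped[:5])
    table = pd.DataFrame(rows, columns=list(STATS_COLUMNS))
    table = table.sort_values(
        ["a", "probe_id"], ascending=[False, True], kind="mergesort",
        ignore_index=True,
    )
    selected = table.loc[table["selected"].astype(bool)]
    up = selected.loc[selected["direction"] == UP, "probe_id"].tolist()
    down = selected.loc[selected["direction"] == DOWN, "probe_id"].tolist()
    logger.info(
        "candidate filter: %d/%d DE probes selected (%d up, %d down)",
        len(up) + len(down), len(de_list), len(up), len(down),
    )
    return up, down, table


def read_candidate_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_candidate_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
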