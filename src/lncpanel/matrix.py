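"""Expression-matrix container conventions and TSV round-trip.

An expression matrix is a pandas DataFrame of non-negative intensities,
indexed by unique probe id, with one column per sample. Sample columns
encode the paired design in their names: ``<pairID>_T`` for the tumor
member and ``<pairID>_N`` for the matched adjacent-normal member of a
pair. Every pair id must appear exactly once per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

TUMOR = "T"
NORMAL = "N"


@dataclass(frozen=True)
class PairedDesign:
    """Sample metadata parsed from matrix column names.

    ``pairs`` is the ordered list of pair ids; ``tumor_cols[i]`` and
    ``normal_cols[i]`` are the two sample columns of ``pairs[i]``.
    """

    pairs: tuple[str, ...]
    tumor_cols: tuple[str, ...]
    normal_cols: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def sample_group(column: str) -> str:
    """Group ('T' or 'N') encoded in a sample column name."""
    pair, _, group = column.rpartition("_")
    if not pair or group not in (TUMOR, NORMAL):
        raise InputError(
            f"sample column {column!r} does not follow the <pair>_T/<pair>_N convention"
        )
    return group


def sample_pair(column: str) -> str:
    """Pair id encoded in a sample column name."""
    sample_group(column)
    return column.rpartition("_")[0]


def paired_design(columns) -> PairedDesign:
    """Parse and validate the paired design from sample column names.

    Raises ``InputError`` naming the offending pair when any pair id does
    not have exactly one tumor and one normal column.
    """
    seen: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for col in columns:
        pair, group = sample_pair(col), sample_group(col)
        if pair not in seen:
            seen[pair] = {}
            order.append(pair)
        if group in seen[pair]:
            raise InputError(f"pair {pair!r} has more than one {group!r} sample")
        seen[pair][group] = col
    incomplete = [p for p in order if len(seen[p]) != 2]
    if incomplete:
        raise InputError(
            "unpaired sample columns for pair id(s): " + ", ".join(incomplete)
        )
    return PairedDesign(
        pairs=tuple(order),
        tumor_cols=tuple(seen[p][TUMOR] for p in order),
        normal_cols=tuple(seen[p][NORMAL] for p in order),
    )


def validate_matrix(matrix: pd.DataFrame) -> PairedDesign:
    """Check matrix invariants (unique probes, non-negative, paired)."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputError("expression matrix is empty")
    if not matrix.index.is_unique:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate probe ids: {dups[:5]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise InputError("expression matrix contains negative intensities")
    return paired_design(matrix.columns)


def read_expression(path) -> pd.DataFrame:
    """Read an expression matrix TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    validate_matrix(df)
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")
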