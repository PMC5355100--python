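"""Hypergeometric over-representation analysis against GMT gene sets.

For a differentially expressed gene list drawn from a finite universe,
each gene set is scored with the exact upper-tail hypergeometric
probability P[X >= x] of observing at least the seen overlap. Sets with
p < 0.05 (strict, uncorrected by default — matching the common
"recommended cutoff" convention of array-vendor pathway tools) are
flagged as enriched. BH adjustment is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a common universe."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        self.sets = {
            name: frozenset(members) & self.universe
            for name, members in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member...).

    When ``universe`` is None it is taken as the union of all members.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed GMT line: {line[:80]!r}")
            name, members = fields[0], frozenset(f for f in fields[2:] if f)
            if name in sets:
                raise InputError(f"duplicate gene-set name {name!r}")
            sets[name] = members
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def hypergeom_pvalue(
    universe_n: int, set_k: int, draw_n: int, overlap_x: int
) -> float:
    """Exact upper-tail hypergeometric probability P[X >= overlap_x].

    X counts the overlap between a fixed set of size ``set_k`` and a draw
    of ``draw_n`` genes without replacement from a universe of size
    ``universe_n``. The observed overlap is included in the tail, so
    overlap 0 gives exactly 1.
    """
    if not (
        0 <= set_k <= universe_n
        and 0 <= draw_n <= universe_n
        and 0 <= overlap_x <= min(set_k, draw_n)
    ):
        raise InputError(
            f"inconsistent hypergeometric counts: N={universe_n} K={set_k} "
            f"n={draw_n} x={overlap_x}"
        )
    if overlap_x == 0:
        return 1.0
    # sum the mass in log space for stability at large N
    support = np.arange(overlap_x, min(set_k, draw_n) + 1)
    logpmf = stats.hypergeom.logpmf(support, universe_n, set_k, draw_n)
    p = float(np.exp(logpmf).sum())
    return min(p, 1.0)


def enrich(
    de_genes,
    collection: GeneSetCollection,
    cutoff: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Score every gene set against a DE gene list.

    Genes outside the universe are dropped with a warning. Returns one
    row per set — overlap count, set size, hypergeometric p, enriched
    flag (p < cutoff, strict) — sorted ascending by p with ties broken by
    set name. ``adjust='bh'`` adds a BH-adjusted column (the enriched
    flag stays on the raw p, matching the uncorrected-cutoff convention).
    """
    if not collection.universe:
        raise InputError("gene-set universe is empty")
    de = set(de_genes)
    outside = de - collection.universe
    if outside:
        logger.warning(
            "dropping %d DE gene(s) outside the universe (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
        de &= collection.universe
    n_universe, n_draw = len(collection.universe), len(de)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        overlap = len(de & members)
        p = hypergeom_pvalue(n_universe, len(members), n_draw, overlap)
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap": overlap,
                "p_value": p,
                "enriched": p < cutoff,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "p_value", "enriched"]
    )
    if adjust == "bh" and len(table):
        table["fdr"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_value", "set_name"], kind="mergesort", ignore_index=True
    )
    return table
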