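"""Positional lncRNA / coding-gene association.

Classifies the genomic relationship between a lncRNA and a coding gene
from their coordinates (0-based, half-open) and tabulates co-aberrant
expression: for each relationship class, how many lncRNAs have a partner
gene that is also differentially expressed, and what fraction of those
pairs change in the same direction.

Relationship classes follow the array-annotation vocabulary: genic
overlaps (sense / antisense / intronic-sense) and near neighbors within a
300 kb window, split into enhancer-like and plain intergenic neighbors.
The enhancer-like vs intergenic distinction cannot be derived from
coordinates and is taken from the lncRNA's annotation class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

# relationship labels
SENSE_OVERLAP = "sense_overlap"
ANTISENSE_OVERLAP = "antisense_overlap"
INTRONIC_SENSE = "intronic_sense"
ENHANCER_NEIGHBOR = "enhancer_like_neighbor"
INTERGENIC_NEIGHBOR = "intergenic_neighbor"
NONE = "none"

RELATIONS = (
    SENSE_OVERLAP,
    ANTISENSE_OVERLAP,
    INTRONIC_SENSE,
    ENHANCER_NEIGHBOR,
    INTERGENIC_NEIGHBOR,
)

# lncRNA annotation classes (vendor-style)
CLASS_GENIC = "genic"
CLASS_ENHANCER = "enhancer_like"
CLASS_INTERGENIC = "intergenic"
CLASS_MRNA = "mrna"

#: default neighbor window in bases (strict upper bound on the gap)
NEIGHBOR_WINDOW = 300_000

ANNOTATION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "probe_id",
    "probe_class",
    "strand",
    "relation",
    "partner_id",
)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise InputError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and (
            self.start < other.end and other.start < self.end
        )


def classify_relation(
    lnc: GenomicInterval,
    gene: GenomicInterval,
    lnc_class: str = CLASS_INTERGENIC,
    neighbor_window: int = NEIGHBOR_WINDOW,
) -> tuple[str, int | None]:
    """Classify the lncRNA-gene relationship; return (relation, distance).

    Overlapping intervals have distance 0; a lncRNA contained in the gene
    on the same strand (and not identical to it) is intronic-sense.
    Disjoint intervals on the same chromosome with a gap strictly below
    ``neighbor_window`` are neighbors, resolved to enhancer-like vs
    intergenic by ``lnc_class``. Different chromosomes, or a gap at or
    beyond the window, give ('none', None).
    """
    if lnc.chrom != gene.chrom:
        return NONE, None
    if lnc.overlaps(gene):
        if lnc.strand != gene.strand:
            return ANTISENSE_OVERLAP, 0
        contained = gene.start <= lnc.start and lnc.end <= gene.end
        identical = lnc.start == gene.start and lnc.end == gene.end
        if contained and not identical:
            return INTRONIC_SENSE, 0
        return SENSE_OVERLAP, 0
    # disjoint, same chromosome: gap between the facing ends
    gap = max(lnc.start, gene.start) - min(lnc.end, gene.end)
    if gap >= neighbor_window:
        return NONE, None
    if lnc_class == CLASS_ENHANCER:
        return ENHANCER_NEIGHBOR, gap
    return INTERGENIC_NEIGHBOR, gap


def read_annotation(path) -> pd.DataFrame:
    """Read the 8-column BED-like probe annotation TSV (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=ANNOTATION_COLUMNS, na_values=[""],
        keep_default_na=False,
    )
    df["partner_id"] = df["partner_id"].replace({"": None})
    return df


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.loc[:, list(ANNOTATION_COLUMNS)].to_csv(
        path, sep="\t", header=False, index=False
    )


def _interval_of(row) -> GenomicInterval:
    return GenomicInterval(
        chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
        strand=row["strand"],
    )


def associate_annotation(
    annot: pd.DataFrame, neighbor_window: int = NEIGHBOR_WINDOW
) -> pd.DataFrame:
    """Build association records from an annotation with partner links.

    Every lncRNA row carrying a partner id is classified against its
    partner's interval. Returns a table (lncrna_id, gene_id, relation,
    distance); pairs classified 'none' are kept so callers can audit them
    but are excluded from summaries downstream.
    """
    by_id = annot.set_index("probe_id")
    if not by_id.index.is_unique:
        raise InputError("annotation probe ids are not unique")
    records = []
    lnc_rows = annot[
        (annot["probe_class"] != CLASS_MRNA) & annot["partner_id"].notna()
    ]
    missing = [
        p for p in lnc_rows["partner_id"] if p not in by_id.index
    ]
    if missing:
        raise InputError(f"annotation partner ids not found: {sorted(set(missing))}")
    for _, row in lnc_rows.iterrows():
        partner = by_id.loc[row["partner_id"]]
        relation, distance = classify_relation(
            _interval_of(row),
            _interval_of(partner),
            lnc_class=row["probe_class"],
            neighbor_window=neighbor_window,
        )
        records.append(
            {
                "lncrna_id": row["probe_id"],
                "gene_id": row["partner_id"],
                "relation": relation,
                "distance": distance,
            }
        )
    return pd.DataFrame(
        records, columns=["lncrna_id", "gene_id", "relation", "distance"]
    )


def coexpression_table(
    de_lnc: pd.DataFrame, de_mrna: pd.DataFrame, associations: pd.DataFrame
) -> pd.DataFrame:
    """Concordance summary per relationship class.

    ``de_lnc`` / ``de_mrna`` are DE tables indexed by probe id with
    ``passes_filter`` and ``direction`` columns. For each relation class
    (excluding 'none') the summary reports the number of DE lncRNAs whose
    partner gene is also DE (``n_co_de``) and, among those pairs, the
    fraction changing in the same direction (``concordant_fraction``).
    """
    if associations.empty:
        return pd.DataFrame(
            columns=["relation", "n_links", "n_co_de", "concordant_fraction"]
        )
    dangling = sorted(
        set(associations["lncrna_id"]) - set(de_lnc.index)
    ) + sorted(set(associations["gene_id"]) - set(de_mrna.index))
    if dangling:
        raise InputError(f"association partners missing from DE tables: {dangling}")
    rows = []
    for relation in RELATIONS:
        sub = associations[associations["relation"] == relation]
        if sub.empty:
            continue
        lnc = de_lnc.loc[sub["lncrna_id"]]
        gene = de_mrna.loc[sub["gene_id"]]
        both_de = (
            lnc["passes_filter"].to_numpy() & gene["passes_filter"].to_numpy()
        )
        n_co = int(both_de.sum())
        same = (
            lnc["direction"].to_numpy()[both_de]
            == gene["direction"].to_numpy()[both_de]
        )
        rows.append(
            {
                "relation": relation,
                "n_links": len(sub),
                "n_co_de": n_co,
                "concordant_fraction": float(same.mean()) if n_co else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["relation", "n_links", "n_co_de", "concordant_fraction"]
    )
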