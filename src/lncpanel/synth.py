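"""Synthetic paired tumor/normal microarray data with known ground truth.

Emulates the study design the pipeline targets: a small number of
matched tumor / adjacent-normal tissue pairs profiled on a combined
lncRNA + mRNA array, with log-normal probe intensities spanning roughly
100-20,000, a planted fraction of differential probes at |log2FC| >= 1,
a per-pair random effect shared by the two members of a pair, and qPCR
crossing-point (Cp) tables derived from expression plus a stable
reference gene.

Everything is driven by one ``SimConfig`` plus a seed; identical config
and seed reproduce byte-identical outputs. Planting uses deterministic
counts (``round(frac * n)``) rather than per-probe coin flips so count
assertions in tests are exact.

A configurable handful of "ideal biomarker" probes is planted with
mid-gate baselines, a large fold change and near-zero within-group
spread — the profile the downstream candidate-selection statistic is
designed to find — giving the end-to-end pipeline a known recovery
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import association as assoc
from .enrichment import GeneSetCollection
from .errors import InputError
from .matrix import NORMAL, TUMOR, sample_group

TRUTH_COLUMNS = (
    "probe_id",
    "probe_class",
    "is_de",
    "log2fc",
    "is_ideal",
    "partner_id",
    "relation",
    "distance",
    "concordant",
)

CLASS_LNCRNA = "lncrna"
CLASS_MRNA = "mrna"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic paired-array experiment.

    Defaults mirror the emulated study design: 3 tumor/normal pairs,
    log2 baselines centered near 9.5 (intensities ~100-20,000 within 2
    SD), ~10% planted differential probes with |log2FC| in [1, 3] and
    balanced signs, a pair random effect and residual noise on the log2
    scale, and 83% same-direction concordance for planted lncRNA-gene
    links.
    """

    n_pairs: int = 3
    n_lncrna: int = 600
    n_mrna: int = 600
    frac_de: float = 0.1
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    baseline_log2_mean: float = 9.5
    baseline_log2_sd: float = 1.5
    pair_sd: float = 0.2
    noise_sd: float = 0.3
    frac_concordant: float = 0.83
    n_ideal_biomarkers: int = 5
    ideal_noise_sd: float = 0.02
    ideal_log2fc: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_lncrna < 1 or self.n_mrna < 1:
            raise InputError("n_pairs, n_lncrna and n_mrna must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise InputError("frac_de must lie in [0, 1]")
        if not 0.0 <= self.frac_concordant <= 1.0:
            raise InputError("frac_concordant must lie in [0, 1]")
        lo, hi = self.log2fc_range
        if not 0 < lo <= hi:
            raise InputError("log2fc_range must satisfy 0 < low <= high")
        for name in ("pair_sd", "noise_sd", "baseline_log2_sd", "ideal_noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.n_ideal_biomarkers < 0:
            raise InputError("n_ideal_biomarkers must be non-negative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _plant_de(rng, n_probes: int, config: SimConfig):
    """Choose DE probes (deterministic count) and signed log2 fold changes."""
    n_de = int(round(config.frac_de * n_probes))
    de_idx = np.sort(rng.choice(n_probes, size=n_de, replace=False))
    n_up = (n_de + 1) // 2
    signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
    signs = rng.permutation(signs)
    magnitudes = rng.uniform(*config.log2fc_range, size=n_de)
    log2fc = np.zeros(n_probes)
    log2fc[de_idx] = signs * magnitudes
    return de_idx, log2fc


def generate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the paired intensity matrix and its ground truth.

    The log2 intensity of probe g in sample (pair i, group t) is
    baseline_g + paireffect_{g,i} + log2fc_g * [t == tumor] + noise,
    exponentiated and clipped at 1 so log transforms stay defined.
    Returns (matrix, truth) with the matrix columns labelled
    ``<pair>_T`` / ``<pair>_N``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_lnc, n_mrna = config.n_lncrna, config.n_mrna
    lnc_ids = [f"LNC{i + 1:05d}" for i in range(n_lnc)]
    mrna_ids = [f"MRNA{i + 1:05d}" for i in range(n_mrna)]
    probe_ids = lnc_ids + mrna_ids
    n_probes = n_lnc + n_mrna

    lnc_de_idx, lnc_fc = _plant_de(rng, n_lnc, config)
    mrna_de_idx, mrna_fc = _plant_de(rng, n_mrna, config)

    # ideal biomarkers: first k planted DE lncRNAs, mid-gate baseline,
    # fixed large |log2FC|, no pair effect, near-zero residual noise
    n_ideal = min(config.n_ideal_biomarkers, len(lnc_de_idx))
    ideal_idx = lnc_de_idx[:n_ideal]
    ideal_baseline = rng.uniform(10.0, 11.0, size=n_ideal)
    lnc_fc[ideal_idx] = np.sign(lnc_fc[ideal_idx]) * config.ideal_log2fc

    # lncRNA-gene links among planted DE probes, cycling relation classes
    n_links = min(len(lnc_de_idx), len(mrna_de_idx))
    link_lnc = lnc_de_idx[:n_links]
    link_mrna = mrna_de_idx[:n_links]
    relations = [assoc.RELATIONS[i % len(assoc.RELATIONS)] for i in range(n_links)]
    distances = rng.integers(10_000, 290_001, size=n_links)
    n_conc = int(round(config.frac_concordant * n_links))
    concordant = rng.permutation(
        np.concatenate([np.ones(n_conc, bool), np.zeros(n_links - n_conc, bool)])
    )
    # partner gene direction follows the planted concordance flag
    for j in range(n_links):
        want = np.sign(lnc_fc[link_lnc[j]]) * (1 if concordant[j] else -1)
        mrna_fc[link_mrna[j]] = want * abs(mrna_fc[link_mrna[j]])

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n_probes
    )
    baseline[ideal_idx] = ideal_baseline
    log2fc = np.concatenate([lnc_fc, mrna_fc])

    pair_scale = np.full(n_probes, config.pair_sd)
    noise_scale = np.full(n_probes, config.noise_sd)
    pair_scale[ideal_idx] = 0.0
    noise_scale[ideal_idx] = min(config.noise_sd, config.ideal_noise_sd)

    pair_eff = rng.standard_normal((n_probes, config.n_pairs)) * pair_scale[:, None]
    noise_t = rng.standard_normal((n_probes, config.n_pairs)) * noise_scale[:, None]
    noise_n = rng.standard_normal((n_probes, config.n_pairs)) * noise_scale[:, None]

    log2_t = baseline[:, None] + pair_eff + log2fc[:, None] + noise_t
    log2_n = baseline[:, None] + pair_eff + noise_n
    intensity_t = np.maximum(np.exp2(log2_t), 1.0)
    intensity_n = np.maximum(np.exp2(log2_n), 1.0)

    columns, data = [], []
    for i in range(config.n_pairs):
        pair = f"P{i + 1:02d}"
        columns += [f"{pair}_{TUMOR}", f"{pair}_{NORMAL}"]
        data += [intensity_t[:, i], intensity_n[:, i]]
    matrix = pd.DataFrame(
        np.column_stack(data), index=pd.Index(probe_ids, name="probe_id"),
        columns=columns,
    )

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "probe_class": [CLASS_LNCRNA] * n_lnc + [CLASS_MRNA] * n_mrna,
            "is_de": log2fc != 0.0,
            "log2fc": log2fc,
            "is_ideal": [i in set(ideal_idx) for i in range(n_lnc)]
            + [False] * n_mrna,
            "partner_id": [None] * n_probes,
            "relation": [assoc.NONE] * n_probes,
            "distance": [np.nan] * n_probes,
            "concordant": pd.Series([pd.NA] * n_probes, dtype="object"),
        }
    )
    for j in range(n_links):
        li, mi = link_lnc[j], n_lnc + link_mrna[j]
        rel = relations[j]
        dist = (
            int(distances[j])
            if rel in (assoc.ENHANCER_NEIGHBOR, assoc.INTERGENIC_NEIGHBOR)
            else 0
        )
        truth.loc[li, ["partner_id", "relation", "distance", "concordant"]] = [
            mrna_ids[link_mrna[j]], rel, dist, bool(concordant[j]),
        ]
        truth.loc[mi, "relation"] = rel  # partner side, for bookkeeping
    return matrix, truth


_LNC_CLASS_BY_RELATION = {
    assoc.SENSE_OVERLAP: assoc.CLASS_GENIC,
    assoc.ANTISENSE_OVERLAP: assoc.CLASS_GENIC,
    assoc.INTRONIC_SENSE: assoc.CLASS_GENIC,
    assoc.ENHANCER_NEIGHBOR: assoc.CLASS_ENHANCER,
    assoc.INTERGENIC_NEIGHBOR: assoc.CLASS_INTERGENIC,
    assoc.NONE: assoc.CLASS_INTERGENIC,
}

_GENE_START, _GENE_END = 1_000, 21_000  # 20 kb gene body


def _lnc_interval(relation: str, distance) -> tuple[int, int, str]:
    """Place the lncRNA relative to the gene so the relation holds."""
    if relation == assoc.SENSE_OVERLAP:
        return 11_000, 31_000, "+"
    if relation == assoc.ANTISENSE_OVERLAP:
        return 11_000, 31_000, "-"
    if relation == assoc.INTRONIC_SENSE:
        return 5_000, 7_000, "+"
    # neighbor: downstream of the gene end with the planted gap
    start = _GENE_END + int(distance)
    return start, start + 2_000, "+"


def generate_annotation(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Probe annotation realizing every planted genomic relationship.

    Each linked lncRNA-gene pair is placed on its own pseudo-chromosome
    so relations hold by construction and nothing overlaps by accident;
    unlinked probes each get a background pseudo-chromosome. Returns the
    8-column BED-like table (chrom, start, end, probe_id, class, strand,
    relation, partner_id).
    """
    config.validate()
    rows: dict[str, dict] = {}
    linked = truth[
        (truth["probe_class"] == CLASS_LNCRNA) & truth["partner_id"].notna()
    ]
    for k, (_, row) in enumerate(linked.iterrows()):
        chrom = f"assoc{k + 1:04d}"
        relation = row["relation"]
        start, end, strand = _lnc_interval(relation, row["distance"])
        rows[row["probe_id"]] = {
            "chrom": chrom, "start": start, "end": end,
            "probe_id": row["probe_id"],
            "probe_class": _LNC_CLASS_BY_RELATION[relation],
            "strand": strand, "relation": relation,
            "partner_id": row["partner_id"],
        }
        rows[row["partner_id"]] = {
            "chrom": chrom, "start": _GENE_START, "end": _GENE_END,
            "probe_id": row["partner_id"], "probe_class": assoc.CLASS_MRNA,
            "strand": "+", "relation": relation, "partner_id": None,
        }
    background = 0
    for _, row in truth.iterrows():
        pid = row["probe_id"]
        if pid in rows:
            continue
        background += 1
        is_lnc = row["probe_class"] == CLASS_LNCRNA
        rows[pid] = {
            "chrom": f"bg{background:05d}", "start": 1_000, "end": 3_000,
            "probe_id": pid,
            "probe_class": assoc.CLASS_INTERGENIC if is_lnc else assoc.CLASS_MRNA,
            "strand": "+", "relation": assoc.NONE, "partner_id": None,
        }
    annot = pd.DataFrame(
        [rows[pid] for pid in truth["probe_id"]],
        columns=list(assoc.ANNOTATION_COLUMNS),
    )
    return annot


def generate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 20,
    set_size: int = 25,
    n_enriched: int = 5,
    de_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str]]:
    """Gene sets over the mRNA universe, some enriched in DE genes.

    The first ``n_enriched`` sets draw ``de_fraction`` of their members
    from planted-DE mRNAs (over-represented by construction); the rest
    are uniform draws. Returns (collection, names of enriched sets).
    """
    rng = np.random.default_rng(seed)
    mrna = truth[truth["probe_class"] == CLASS_MRNA]
    universe = mrna["probe_id"].tolist()
    de_genes = mrna.loc[mrna["is_de"], "probe_id"].tolist()
    other = mrna.loc[~mrna["is_de"], "probe_id"].tolist()
    if set_size > len(universe):
        raise InputError("set_size exceeds the mRNA universe")
    sets: dict[str, frozenset] = {}
    enriched_names = []
    for s in range(n_sets):
        name = f"SET{s + 1:03d}"
        if s < n_enriched and de_genes:
            n_from_de = min(int(round(de_fraction * set_size)), len(de_genes))
            members = list(rng.choice(de_genes, n_from_de, replace=False))
            members += list(
                rng.choice(other, min(set_size - n_from_de, len(other)), replace=False)
            )
            enriched_names.append(name)
        else:
            members = list(rng.choice(universe, set_size, replace=False))
        sets[name] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), enriched_names


def generate_cp_table(
    expression: pd.DataFrame,
    c0: float = 30.0,
    cp_noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "ACTB",
    reference_level: float = 1.0,
) -> pd.DataFrame:
    """Replicate Cp table from per-sample relative expression levels.

    ``expression`` is samples (rows, named ``<pair>_T/N``) x genes of
    positive expression levels; each (sample, gene) yields
    ``n_replicates`` crossing points Cp = c0 - log2(expression) + noise,
    the qPCR identity that one cycle equals a twofold template change. A
    reference gene with planted constant expression is appended. Returns
    a tidy table (sample, group, gene, replicate, cp).
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    values = expression.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        raise InputError("expression levels must be positive and finite")
    if reference_gene in expression.columns:
        raise InputError(f"reference gene {reference_gene!r} collides with a marker")
    rng = np.random.default_rng(seed)
    full = expression.copy()
    full[reference_gene] = reference_level
    records = []
    for sample in full.index:
        group = "tumor" if sample_group(sample) == TUMOR else "normal"
        for gene in full.columns:
            base = c0 - np.log2(full.loc[sample, gene])
            noise = rng.normal(0.0, cp_noise_sd, size=n_replicates)
            for r in range(n_replicates):
                records.append(
                    {
                        "sample": sample, "group": group, "gene": gene,
                        "replicate": r + 1, "cp": base + noise[r],
                    }
                )
    return pd.DataFrame(records, columns=["sample", "group", "gene", "replicate", "cp"])


def simulate_marker_expression(
    marker_log2fc: dict[str, float],
    n_pairs: int,
    shared_sd: float = 1.2,
    marker_sd: float = 1.6,
    seed: int = 0,
    pair_prefix: str = "Q",
) -> pd.DataFrame:
    """Per-sample expression of a marker panel in a qPCR cohort.

    Each tissue sample carries a shared subject-level log2 factor
    (correlating the markers, as co-regulated transcripts in one tissue
    are) plus marker-specific biological noise; tumor samples add the
    marker's log2 effect. Returns samples x markers expression levels
    (relative scale, centered at 1 for an average normal sample).
    """
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    markers = list(marker_log2fc)
    samples, rows = [], []
    for i in range(n_pairs):
        pair = f"{pair_prefix}{i + 1:03d}"
        for group in (TUMOR, NORMAL):
            shared = rng.normal(0.0, shared_sd)
            eps = rng.normal(0.0, marker_sd, size=len(markers))
            effect = np.array(
                [marker_log2fc[m] if group == TUMOR else 0.0 for m in markers]
            )
            samples.append(f"{pair}_{group}")
            rows.append(np.exp2(shared + eps + effect))
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample"), columns=markers)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"truth table missing columns: {missing}")
    return df
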