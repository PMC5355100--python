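"""End-to-end orchestration of the discovery -> validation funnel.

Stages: simulate -> de -> associate -> enrich -> select -> qpcr -> roc,
mirroring the array-discovery / candidate-filter / qPCR-validation flow
of a paired biomarker study. Stages communicate only via files
(TSV/CSV/GMT) so each is independently runnable and inspectable; a JSON
manifest records parameters, seeds, record counts and SHA-256 checksums
of every output so a rerun with the same config is verifiably
identical.

The qpcr stage simulates training and validation cohorts for the top
selected candidates (their planted effects read from the ground truth,
standing in for the biology the wet lab would measure), quantifies them
by 2^-ddCp with a group-mean-of-normals calibrator, and the roc stage
fits the logistic panel on training only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, candidates, de, diagnostics, qpcr, synth
from .errors import InputError
from .matrix import TUMOR, read_expression, sample_group, write_expression

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "associate", "enrich", "select", "qpcr", "roc")


@dataclass
class RunConfig:
    """All pipeline stage parameters in one reproducible bundle."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    # de stage
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    test_mode: str = "two_sample"
    pseudocount: float = 1.0
    # association stage
    neighbor_window: int = association.NEIGHBOR_WINDOW
    # enrichment stage
    enrich_cutoff: float = 0.05
    n_gene_sets: int = 20
    gene_set_size: int = 25
    # candidate stage
    gate_low: float = candidates.GATE_LOW
    gate_high: float = candidates.GATE_HIGH
    ratio: float = 10.0
    # qpcr / roc stages
    n_panel: int = 5
    n_train_pairs: int = 24
    n_valid_pairs: int = 39
    cp_baseline: float = 30.0
    cp_noise_sd: float = 0.15
    n_replicates: int = 3
    reference_gene: str = "ACTB"
    calibrator: str = qpcr.GROUP_MEAN_NORMAL
    qpcr_shared_sd: float = 1.2
    qpcr_marker_sd: float = 1.6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError("config file must be a key-value mapping")
        sim_kwargs = raw.pop("sim", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        try:
            sim = synth.SimConfig(**sim_kwargs)
        except TypeError as exc:
            raise InputError(f"invalid sim config: {exc}") from exc
        cfg = cls(sim=sim, **raw)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["log2fc_range"] = list(d["sim"]["log2fc_range"])
        d["stages"] = list(d["stages"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _labels(samples) -> list[int]:
    return [1 if sample_group(s) == TUMOR else 0 for s in samples]


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages, writing outputs and a manifest.

    ``seed`` overrides the config seed (and reseeds the simulation);
    derived stage seeds are small fixed offsets so stages stay
    independent. Returns the manifest dict (also written as
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    base_seed = config.seed
    config = dataclasses.replace(config, sim=config.sim.with_seed(base_seed))
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise InputError(f"unknown stage(s): {sorted(unknown)}")

    manifest: dict = {
        "package": "lncpanel",
        "version": __version__,
        "seed": base_seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]):
        manifest["stages"][stage] = {
            "outputs": {name: str(p.name) for name, p in files.items()},
            "checksums": {name: _sha256(p) for name, p in files.items()},
            "counts": counts,
        }
        logger.info("stage %s: %s", stage, counts)

    current = None  # raises clearly if a stage is toggled off but needed
    try:
        if "simulate" in config.stages:
            current = "simulate"
            matrix, truth = synth.generate_expression(config.sim)
            annot = synth.generate_annotation(config.sim, truth)
            collection, enriched = synth.generate_gene_sets(
                truth, n_sets=config.n_gene_sets, set_size=config.gene_set_size,
                seed=base_seed + 1,
            )
            write_expression(matrix, out / "expression_raw.tsv")
            synth.write_truth(truth, out / "ground_truth.tsv")
            association.write_annotation(annot, out / "annotation.tsv")
            from .enrichment import write_gmt

            write_gmt(collection, out / "gene_sets.gmt")
            record(
                "simulate",
                {
                    "expression": out / "expression_raw.tsv",
                    "truth": out / "ground_truth.tsv",
                    "annotation": out / "annotation.tsv",
                    "gene_sets": out / "gene_sets.gmt",
                },
                {
                    "probes": len(matrix),
                    "samples": matrix.shape[1],
                    "planted_de": int(truth["is_de"].sum()),
                    "enriched_sets": len(enriched),
                },
            )

        if "de" in config.stages:
            current = "de"
            matrix = read_expression(out / "expression_raw.tsv")
            normalized = de.quantile_normalize(matrix)
            write_expression(normalized, out / "expression_normalized.tsv")
            annot = association.read_annotation(out / "annotation.tsv")
            classes = annot.set_index("probe_id")["probe_class"].map(
                lambda c: "mrna" if c == association.CLASS_MRNA else "lncrna"
            )
            table = de.de_table(
                normalized,
                pseudocount=config.pseudocount,
                test_mode=config.test_mode,
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold,
                probe_classes=classes,
            )
            table["probe_class"] = classes.reindex(table.index)
            de.write_de_table(table, out / "de_results.tsv")
            record(
                "de",
                {
                    "normalized": out / "expression_normalized.tsv",
                    "de_results": out / "de_results.tsv",
                },
                {
                    "probes": len(table),
                    "de_pass": int(table["passes_filter"].sum()),
                    "up": int((table["direction"] == de.UP).sum()),
                    "down": int((table["direction"] == de.DOWN).sum()),
                },
            )

        de_results = None
        if {"associate", "enrich", "select", "qpcr", "roc"} & set(config.stages):
            de_results = de.read_de_table(out / "de_results.tsv")

        if "associate" in config.stages:
            current = "associate"
            annot = association.read_annotation(out / "annotation.tsv")
            records = association.associate_annotation(
                annot, neighbor_window=config.neighbor_window
            )
            lnc = de_results[de_results["probe_class"] == "lncrna"]
            mrna = de_results[de_results["probe_class"] == "mrna"]
            summary = association.coexpression_table(lnc, mrna, records)
            records.to_csv(out / "associations.tsv", sep="\t", index=False)
            summary.to_csv(out / "coexpression_summary.tsv", sep="\t", index=False)
            record(
                "associate",
                {
                    "associations": out / "associations.tsv",
                    "summary": out / "coexpression_summary.tsv",
                },
                {"links": len(records), "classes": len(summary)},
            )

        if "enrich" in config.stages:
            current = "enrich"
            from .enrichment import enrich, read_gmt

            collection = read_gmt(out / "gene_sets.gmt")
            mrna = de_results[de_results["probe_class"] == "mrna"]
            de_genes = mrna.index[mrna["passes_filter"]].tolist()
            # universe = every assayed mRNA, not just set members
            collection.universe = frozenset(mrna.index)
            table = enrich(de_genes, collection, cutoff=config.enrich_cutoff)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record(
                "enrich",
                {"enrichment": out / "enrichment.tsv"},
                {"sets": len(table), "enriched": int(table["enriched"].sum())},
            )

        if "select" in config.stages:
            current = "select"
            raw = read_expression(out / "expression_raw.tsv")
            lnc = de_results[de_results["probe_class"] == "lncrna"]
            de_list = lnc.index[lnc["passes_filter"]].tolist()
            up, down, stats = candidates.select_candidates(
                raw, de_list,
                gate=(config.gate_low, config.gate_high), ratio=config.ratio,
            )
            candidates.write_candidate_table(stats, out / "candidates.tsv")
            record(
                "select",
                {"candidates": out / "candidates.tsv"},
                {"de_lncrna": len(de_list), "up": len(up), "down": len(down)},
            )

        if "qpcr" in config.stages:
            current = "qpcr"
            stats = candidates.read_candidate_table(out / "candidates.tsv")
            panel_ids = stats.loc[stats["selected"], "probe_id"].head(
                config.n_panel
            ).tolist()
            if not panel_ids:
                raise InputError("no selected candidates to carry into qPCR")
            truth = synth.read_truth(out / "ground_truth.tsv").set_index("probe_id")
            marker_fc = {m: float(truth.loc[m, "log2fc"]) for m in panel_ids}
            files, counts = {}, {}
            for cohort, n_pairs, offset in (
                ("train", config.n_train_pairs, 2),
                ("valid", config.n_valid_pairs, 3),
            ):
                expr = synth.simulate_marker_expression(
                    marker_fc, n_pairs,
                    shared_sd=config.qpcr_shared_sd,
                    marker_sd=config.qpcr_marker_sd,
                    seed=base_seed + offset, pair_prefix=cohort[0].upper() + "Q",
                )
                cp = synth.generate_cp_table(
                    expr, c0=config.cp_baseline, cp_noise_sd=config.cp_noise_sd,
                    n_replicates=config.n_replicates, seed=base_seed + offset + 10,
                    reference_gene=config.reference_gene,
                )
                qpcr.write_cp_table(cp, out / f"cp_{cohort}.csv")
                rel = qpcr.relative_expression(
                    cp, reference_gene=config.reference_gene,
                    calibrator=config.calibrator,
                )
                rel.to_csv(out / f"qpcr_{cohort}.tsv", sep="\t", index=False)
                files[f"cp_{cohort}"] = out / f"cp_{cohort}.csv"
                files[f"qpcr_{cohort}"] = out / f"qpcr_{cohort}.tsv"
                counts[f"{cohort}_samples"] = 2 * n_pairs
            counts["markers"] = len(panel_ids)
            record("qpcr", files, counts)

        if "roc" in config.stages:
            current = "roc"
            cohorts = {}
            for cohort in ("train", "valid"):
                rel = pd.read_csv(out / f"qpcr_{cohort}.tsv", sep="\t")
                wide = rel.pivot(index="sample", columns="gene", values="rel_expr")
                cohorts[cohort] = (wide, _labels(wide.index))
            report, panel = diagnostics.evaluate_cohorts(
                cohorts["train"][0], cohorts["train"][1],
                cohorts["valid"][0], cohorts["valid"][1],
            )
            report.to_csv(out / "roc_report.tsv", sep="\t", index=False)
            record(
                "roc",
                {"roc_report": out / "roc_report.tsv"},
                {"markers": len(panel.markers), "rows": len(report)},
            )
    except OSError as exc:
        # missing/unreadable stage files are an input problem; OSError
        # formats its message from errno fields, so re-wrap to name the stage
        raise InputError(f"stage {current!r} failed: {exc}") from exc
    except Exception as exc:
        # name the failing stage but keep the exception type (exit codes)
        exc.args = (f"stage {current!r} failed: {exc}",)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
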