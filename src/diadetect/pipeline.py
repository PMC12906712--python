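"""End-to-end pipeline orchestration and configuration.

``run_pipeline`` chains filter → quantify → detect → classify → cohort
statistics and writes the standard output bundle: filtered report,
per-run counts, protein matrix, detection matrix, classification table,
Venn counts, PCA scores, and a log with the configuration hash.  The
pipeline is fully deterministic: identical inputs and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from diadetect import cohort
from diadetect.detection import (
    RuleSet,
    build_detection_matrix,
    classify_all,
    detection_summary,
    preferred_sets,
    sensitivity_scan,
)
from diadetect.diann_io import (
    FilterConfig,
    apply_filters,
    load_contaminants,
    per_run_counts,
    read_metadata,
    read_report,
    write_report,
)
from diadetect.quant import quantify_all

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "filtered_report.tsv",
    "per_run_counts.tsv",
    "protein_matrix.tsv",
    "detection_matrix.tsv",
    "classification.tsv",
    "venn.json",
    "pca_scores.tsv",
    "stats.json",
)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run; round-trips via YAML."""

    report_path: str = ""
    metadata_path: str = ""
    contaminants_path: str | None = None
    output_dir: str = "diadetect_out"
    q_max: float = 0.01
    drop_contaminants: bool = True
    strong_min_frac_dep: float = 0.75
    strong_min_frac_nondep: float = 0.80
    moderate_min_frac_dep: float = 0.50
    moderate_min_frac_nondep: float = 0.60
    other_max_count: int = 1
    preferred_min_count: int = 2
    pca_impute_half_min: bool = False
    sensitivity_grid: list[list[int]] = field(
        default_factory=lambda: [[2, 1], [3, 1], [4, 1], [2, 0], [3, 0], [4, 0]]
    )
    digest_max_missed: int = 1
    digest_trypsin_p: bool = True

    def rule_set(self) -> RuleSet:
        return RuleSet(
            strong_min_frac_dep=self.strong_min_frac_dep,
            strong_min_frac_nondep=self.strong_min_frac_nondep,
            moderate_min_frac_dep=self.moderate_min_frac_dep,
            moderate_min_frac_nondep=self.moderate_min_frac_nondep,
            other_max_count=self.other_max_count,
            preferred_min_count=self.preferred_min_count,
        )

    def filter_config(self, contaminants: frozenset[str]) -> FilterConfig:
        return FilterConfig(
            q_max=self.q_max,
            contaminant_accessions=contaminants,
            drop_contaminants=self.drop_contaminants,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # output_dir is excluded: where results land must not change them
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write the output bundle.

    Returns a mapping of output name → path.  Any stage failure removes
    partially written outputs and raises :class:`PipelineStageError`
    naming the stage.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        records = read_report(cfg.report_path)
        meta = read_metadata(cfg.metadata_path)
        contaminants = (
            load_contaminants(cfg.contaminants_path) if cfg.contaminants_path else frozenset()
        )

        stage = "filter"
        filtered = apply_filters(records, cfg.filter_config(contaminants))
        path = out_dir / "filtered_report.tsv"
        write_report(filtered, path)
        written.append(path)
        counts = per_run_counts(filtered, meta)
        path = out_dir / "per_run_counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        written.append(path)

        stage = "quantify"
        quant = quantify_all(filtered, meta)
        path = out_dir / "protein_matrix.tsv"
        quant.to_csv(path, sep="\t", na_rep="")
        written.append(path)

        stage = "detect"
        detected = build_detection_matrix(quant, meta)
        path = out_dir / "detection_matrix.tsv"
        detected.astype(int).to_csv(path, sep="\t")
        written.append(path)
        summary = detection_summary(detected, meta)

        stage = "classify"
        rules = cfg.rule_set()
        classification = classify_all(summary, rules)
        genes = (
            filtered.groupby("protein_group")["genes"].first()
            if len(filtered)
            else None
        )
        if genes is not None:
            classification.insert(0, "genes", classification.index.map(genes).fillna(""))
        path = out_dir / "classification.tsv"
        classification.to_csv(path, sep="\t", index_label="protein")
        written.append(path)
        sets = preferred_sets(summary, rules)
        venn = {
            "dep": len(sets["dep_preferred"]),
            "nondep": len(sets["nondep_preferred"]),
            "shared": len(sets["shared"]),
        }
        venn["total"] = venn["dep"] + venn["nondep"] + venn["shared"]
        path = out_dir / "venn.json"
        path.write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        written.append(path)
        scan = sensitivity_scan(summary, [tuple(pair) for pair in cfg.sensitivity_grid])

        stage = "stats"
        dep_counts = counts.loc[counts["group"] == "Dep", "n_proteins"]
        nondep_counts = counts.loc[counts["group"] == "NonDep", "n_proteins"]
        stats_out: dict = {
            "config_hash": cfg.config_hash(),
            "n_records_in": int(len(records)),
            "n_records_filtered": int(len(filtered)),
            "sensitivity_scan": scan.to_dict(orient="records"),
        }
        if len(dep_counts) >= 2 and len(nondep_counts) >= 2:
            stats_out["id_count_comparison"] = cohort.compare_id_counts(
                dep_counts, nondep_counts
            )
        try:
            pca = cohort.pca_replicates(quant, impute_half_min=cfg.pca_impute_half_min)
            path = out_dir / "pca_scores.tsv"
            pca["scores"].to_csv(path, sep="\t", index_label="run_id")
            written.append(path)
            stats_out["pca_variance_fractions"] = pca["variance_fractions"]
        except ValueError as exc:
            stats_out["pca_error"] = str(exc)
            path = out_dir / "pca_scores.tsv"
            path.write_text("run_id\n")
            written.append(path)
        path = out_dir / "stats.json"
        path.write_text(json.dumps(stats_out, indent=2, sort_keys=True) + "\n")
        written.append(path)

        log_path = out_dir / "pipeline.log"
        log_path.write_text(
            f"diadetect pipeline\nconfig_hash: {cfg.config_hash()}\n"
            f"records_in: {len(records)}\nrecords_filtered: {len(filtered)}\n"
            f"outputs: {', '.join(p.name for p in written)}\n"
        )
        written.append(log_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineStageError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {p.name: p for p in written}
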