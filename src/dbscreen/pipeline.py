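"""End-to-end orchestration: simulate -> preprocess -> reference/screen ->
differential expression -> secondary markers -> mutation evaluation.

``run_pipeline`` writes one TSV per stage plus a JSON manifest recording
inputs, parameters, the seed and a checksum per output file; the same
config and seed reproduce byte-identical outputs.  All outputs are keyed
by protein symbol and sample id, never by position.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .differential import DepConfig, dep_table
from .enrichment import MarkerConfig, dual_control_markers
from .matrix import NormalizedMatrix, ValidationError
from .mutloss import StabilityRule, evaluate_missense_predictions
from .preprocess import (
    ImputeParams,
    filter_by_evidence,
    impute_downshift,
    log2_transform,
    normalize_actb,
)
from .screen import (
    DEFAULT_PANELS,
    FlagRule,
    ReferenceIntervalScreen,
    correlation_matrix,
    panel_scores,
)
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger("dbscreen")


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    Exactly one of (``matrix_path`` + ``meta_path``) or ``cohort`` must be
    supplied.
    """

    outdir: str = "dbscreen_out"
    matrix_path: str | None = None
    meta_path: str | None = None
    genesets_path: str | None = None
    mutations_path: str | None = None
    cohort: CohortConfig | None = None
    min_peptides: int = 2
    impute: ImputeParams = field(default_factory=ImputeParams)
    dep: DepConfig = field(default_factory=DepConfig)
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    flag_rule: FlagRule = field(default_factory=FlagRule)
    stability: StabilityRule = field(default_factory=StabilityRule)
    seed: int = 0

    def __post_init__(self) -> None:
        from_paths = self.matrix_path is not None and self.meta_path is not None
        from_cohort = self.cohort is not None
        if from_paths == from_cohort:
            raise ValidationError(
                "supply exactly one of (matrix_path + meta_path) or a cohort config"
            )


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name, so a
    stage reproduces regardless of the order stages run in."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save_df(name: str, df: pd.DataFrame, index_label: str) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index_label=index_label)
        written[name] = path

    # ---- input stage ----------------------------------------------------
    if config.cohort is not None:
        cohort_cfg = config.cohort
        cohort_cfg.seed = stage_seed(config.seed, "simulate")
        logger.info("simulating cohort (seed %d)", cohort_cfg.seed)
        matrix, meta, truth = generate_cohort(cohort_cfg)
        dio.write_abundance_matrix(matrix, outdir / "matrix.tsv")
        written["matrix"] = outdir / "matrix.tsv"
        dio.write_sample_meta(meta, outdir / "meta.tsv")
        written["meta"] = outdir / "meta.tsv"
        save_df("truth_effects", truth.effects, "effect_id")
    else:
        matrix = dio.read_abundance_matrix(config.matrix_path)
        meta = dio.read_sample_meta(config.meta_path)
    missing = set(meta.index) - set(matrix.samples)
    if missing:
        raise ValidationError(f"metadata samples absent from matrix: {sorted(missing)}")

    newborns = list(meta.index[meta["group"] == "healthy_newborn"])
    adults = list(meta.index[meta["group"] == "healthy_adult"])
    patients = meta[meta["group"] == "patient"]

    # ---- preprocess ------------------------------------------------------
    logger.info("preprocess: evidence filter + %%beta-actin + log2 + imputation")
    filtered = filter_by_evidence(matrix, config.min_peptides, newborns or None)
    normalized = normalize_actb(filtered)
    logged = log2_transform(normalized)
    impute_params = ImputeParams(
        config.impute.width, config.impute.downshift,
        stage_seed(config.seed, "impute"),
    )
    imputed = impute_downshift(logged, impute_params)
    dio.write_normalized_matrix(imputed, outdir / "log2_imputed.tsv")
    written["log2_imputed"] = outdir / "log2_imputed.tsv"
    linear = NormalizedMatrix(np.exp2(imputed.values), "percent_actb")

    # ---- reference + screening ------------------------------------------
    logger.info("screening against the healthy-newborn reference")
    screen = ReferenceIntervalScreen(
        config.flag_rule.rule_name, config.flag_rule.z_cut
    ).fit(linear, meta)
    save_df("reference_newborn", screen.reference_.table, "protein")

    screening_report = None
    if len(patients):
        targets = patients["causative_gene"].dropna()
        screening_report = screen.screen_targets(
            linear.values, targets, normalized.below_lod
        )
        usable_panels = {
            k: v for k, v in DEFAULT_PANELS.items()
            if any(p in linear.proteins for p in v)
        }
        if usable_panels:
            scores = panel_scores(
                linear.values[list(patients.index)], screen.reference_, usable_panels
            )
            screening_report = screening_report.join(scores.add_prefix("panel_"))
        save_df("screening_report", screening_report, "sample")

    save_df("correlation_samples", correlation_matrix(imputed.values), "sample")

    # ---- differential expression ----------------------------------------
    deps = {}
    if len(newborns) >= 2 and len(adults) >= 2:
        logger.info("DEP stage: newborn vs adult")
        deps["newborn_vs_adult"] = dep_table(
            imputed.values, newborns, adults, config.dep
        )
        save_df("dep_newborn_vs_adult", deps["newborn_vs_adult"], "protein")

    # ---- secondary markers per disease ----------------------------------
    genesets = None
    if config.genesets_path:
        genesets = dio.read_gene_sets(config.genesets_path)
    elif config.cohort is not None:
        from .simulate import demo_gene_sets

        genesets = demo_gene_sets(seed=stage_seed(config.seed, "genesets"))
    markers = {}
    if genesets is not None and len(patients):
        universe = list(imputed.proteins)
        for disease, group in patients.groupby("disease"):
            cols = list(group.index)
            if len(cols) < 2:
                logger.info("skipping markers for %s (<2 samples)", disease)
                continue
            d_nb = dep_table(imputed.values, cols, newborns, config.dep)
            d_ad = dep_table(imputed.values, cols, adults, config.dep)
            report = dual_control_markers(
                d_nb, d_ad, genesets.restricted_to(universe), universe, config.marker
            )
            markers[disease] = report
            save_df(f"markers_{disease}", report.set_index("marker") if len(report)
                    else report, "marker")

    # ---- mutation-loss evaluation ---------------------------------------
    confusion = None
    if config.mutations_path:
        records = dio.read_mutation_table(config.mutations_path)
        confusion = evaluate_missense_predictions(records, config.stability)
        path = outdir / "mutation_confusion.json"
        path.write_text(json.dumps(confusion.as_dict(), indent=2) + "\n")
        written["mutation_confusion"] = path

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "parameters": {
            "min_peptides": config.min_peptides,
            "impute": asdict(config.impute),
            "dep": asdict(config.dep),
            "marker": asdict(config.marker),
            "flag_rule": asdict(config.flag_rule),
            "stability": asdict(config.stability),
        },
        "inputs": {
            "matrix_path": config.matrix_path,
            "meta_path": config.meta_path,
            "genesets_path": config.genesets_path,
            "mutations_path": config.mutations_path,
            "simulated": config.cohort is not None,
        },
        "n_samples": int(len(meta)),
        "n_proteins_input": int(len(matrix.proteins)),
        "n_proteins_filtered": int(len(filtered.proteins)),
        "outputs": {name: {"path": str(p), "sha256": _checksum(p)}
                    for name, p in sorted(written.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def report_summary(outdir: str | Path) -> str:
    """Human-readable per-patient summary of a completed run."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest in {outdir}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "screening summary",
        f"  proteins: {manifest['n_proteins_input']} input, "
        f"{manifest['n_proteins_filtered']} after evidence filter",
        f"  samples: {manifest['n_samples']}",
    ]
    report_path = outdir / "screening_report.tsv"
    if report_path.exists():
        report = pd.read_csv(report_path, sep="\t")
        lines.append("  patients:")
        for _, row in report.iterrows():
            panels = [
                f"{c.removeprefix('panel_')}={row[c]:+.1f}"
                for c in report.columns if c.startswith("panel_")
            ]
            value = "<LOD" if row.get("below_lod") else f"{row['value']:.3g}"
            lines.append(
                f"    {row['sample']}: {row['protein']} {value} "
                f"flag={row['flag']} ({row['rationale']}) "
                + (" ".join(panels) if panels else "")
            )
    else:
        lines.append("  patients: none")
    marker_files = sorted(outdir.glob("markers_*.tsv"))
    for mf in marker_files:
        markers = pd.read_csv(mf, sep="\t")
        name = mf.stem.removeprefix("markers_")
        hits = ", ".join(markers["marker"].astype(str)) if len(markers) else "none"
        lines.append(f"  secondary markers [{name}]: {hits}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# deposited-cohort replication
# ---------------------------------------------------------------------------


def cohort_summary(
    matrix_path: str | Path,
    meta_path: str | Path,
    min_peptides: int = 2,
    dep_config: DepConfig | None = None,
    impute_seed: int = 0,
) -> dict:
    """Summary statistics of a full quantification cohort.

    Designed to replicate a deposited study table: the >=2-peptide +
    complete-in-newborns filter count, the newborn-vs-adult DEP up/down
    counts, and the within-newborn pairwise Pearson correlation range.
    """
    matrix = dio.read_abundance_matrix(matrix_path)
    meta = dio.read_sample_meta(meta_path)
    newborns = list(meta.index[meta["group"] == "healthy_newborn"])
    adults = list(meta.index[meta["group"] == "healthy_adult"])
    filtered = filter_by_evidence(matrix, min_peptides, newborns)
    logged = log2_transform(normalize_actb(filtered))
    imputed = impute_downshift(logged, ImputeParams(seed=impute_seed))
    deps = dep_table(imputed.values, newborns, adults, dep_config or DepConfig())
    corr = correlation_matrix(imputed.values, newborns)
    off_diag = corr.to_numpy()[~np.eye(len(newborns), dtype=bool)]
    return {
        "n_proteins_total": int(len(matrix.proteins)),
        "n_proteins_filtered": int(len(filtered.proteins)),
        "n_dep_up": int((deps["is_dep"] & (deps["direction"] == "up")).sum()),
        "n_dep_down": int((deps["is_dep"] & (deps["direction"] == "down")).sum()),
        "newborn_pearson_min": float(off_diag.min()),
        "newborn_pearson_max": float(off_diag.max()),
    }
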