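"""End-to-end orchestration: digestion scoring → curation → classification →
quantification → set comparison, with deterministic, provenance-stamped
TSV/JSON outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .glyco_digest import cirfess_score
from .markers import AbundanceProfile, score_markers
from .proteome_io import (
    load_surface_predictions,
    load_topology,
    parse_fasta,
)
from .psm_curation import (
    ProteinEvidenceSummary,
    assign_master_proteins,
    classify_surface,
    compute_specificity,
    infer_orientation,
    parse_psm_table,
    curation_report,
)
from .quant import (
    differential_test,
    equalize_medians,
    impute_censored,
    log2_transform,
    summarize_runs,
)
from .sets import exclusive_intersections

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


def _config_hash(config: RunConfig) -> str:
    # out_dir is excluded: where outputs land must not change their bytes
    payload = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, provenance: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage the config provides inputs for.

    Outputs are deterministic given inputs and seed.  On a stage failure the
    partial outputs are removed and a stage-named :class:`PipelineError` is
    raised.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = f"# surfacer v{__version__} config_hash={_config_hash(config)}\n"
    outputs: dict[str, Path] = {}

    def emit(name: str, filename: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / filename
        _write_table(df, path, provenance, index)
        outputs[name] = path

    stage = "io"
    try:
        if not config.fasta:
            raise PipelineError("stage io: no FASTA input configured")
        proteins = parse_fasta(config.fasta)
        protein_map = {p.accession: p for p in proteins}
        topology = (
            load_topology(config.topology, proteins) if config.topology else {}
        )
        surface = (
            load_surface_predictions(config.surface_predictions, proteins)
            if config.surface_predictions
            else {}
        )

        stage = "digest-score"
        cirfess = {}
        cirfess_rows = []
        for protein in proteins:
            annotation = surface.get(protein.accession)
            has_sp = bool(
                annotation and annotation.has_signal_peptide(config.signal_peptide_rule)
            )
            result = cirfess_score(
                protein,
                topology.get(protein.accession, ()),
                has_signal_peptide=has_sp,
                missed_cleavages=config.missed_cleavages,
                include_nxc=config.include_nxc,
            )
            cirfess[protein.accession] = result
            cirfess_rows.append(
                {
                    "accession": protein.accession,
                    "cirfess_score": result.score,
                    "topology_source": result.topology_source,
                    "peptides": ";".join(
                        p.sequence for p, _s in result.contributing
                    ),
                }
            )
        emit("cirfess", "cirfess.tsv", pd.DataFrame(cirfess_rows))

        stage = "classify"
        classification_rows = []
        classifications_all = {}
        for protein in proteins:
            annotation = surface.get(protein.accession)
            summary_like = ProteinEvidenceSummary(
                accession=protein.accession,
                cirfess_score=cirfess[protein.accession].score,
                spc_score=annotation.spc_score if annotation else 0,
                signal_peptide=bool(
                    annotation
                    and annotation.has_signal_peptide(config.signal_peptide_rule)
                ),
            )
            verdict = classify_surface(summary_like)
            classifications_all[protein.accession] = verdict
            classification_rows.append(
                {
                    "accession": protein.accession,
                    "cirfess_score": summary_like.cirfess_score,
                    "spc_score": summary_like.spc_score,
                    "signal_peptide": summary_like.signal_peptide,
                    "is_surface": verdict.is_surface,
                    "branch": verdict.branch,
                }
            )
        emit("classification", "classification.tsv", pd.DataFrame(classification_rows))

        if config.psm_table:
            stage = "curate"
            psms, n_bad = parse_psm_table(config.psm_table, config.dialect)
            if n_bad:
                logger.warning("%d PSM rows dropped (bad modifications)", n_bad)
            summaries = assign_master_proteins(
                psms, protein_map, include_nxc=config.include_nxc
            )
            for accession, summary in summaries.items():
                summary.cirfess_score = cirfess[accession].score if accession in cirfess else 0
                annotation = surface.get(accession)
                summary.spc_score = annotation.spc_score if annotation else 0
                summary.signal_peptide = bool(
                    annotation
                    and annotation.has_signal_peptide(config.signal_peptide_rule)
                )
            specificity = compute_specificity(
                summaries, psms, protein_map, include_nxc=config.include_nxc
            )
            classifications = {
                a: classify_surface(s) for a, s in summaries.items()
            }
            report = curation_report(summaries, classifications, specificity)
            emit("scm", "scm.tsv", report["scm"])
            emit("scm_filtered", "scm_filtered.tsv", report["scm_filtered"])
            emit("glycosites", "glycosites.tsv", report["glycosites"])
            spec_path = out_dir / "specificity.json"
            spec_path.write_text(
                json.dumps(dataclasses.asdict(specificity), indent=1, sort_keys=True)
            )
            outputs["specificity"] = spec_path

            stage = "orientation"
            orientation_rows = []
            for accession in sorted(summaries):
                summary = summaries[accession]
                sites = [g.position for g in summary.glycosites]
                for annotation in topology.get(accession, []):
                    if not annotation.regions_with_label("transmembrane"):
                        continue
                    verdict = infer_orientation(sites, annotation)
                    orientation_rows.append(
                        {
                            "accession": accession,
                            "predictor": annotation.predictor,
                            "inferred": verdict.inferred,
                            "status": verdict.status,
                            "n_glycosites": len(sites),
                        }
                    )
            emit(
                "orientation",
                "orientation.tsv",
                pd.DataFrame(
                    orientation_rows,
                    columns=["accession", "predictor", "inferred", "status", "n_glycosites"],
                ),
            )

        if config.intensity_matrix and config.design:
            stage = "quant"
            raw = pd.read_csv(
                config.intensity_matrix, sep="\t", comment="#",
                index_col=[0, 1],
            )
            design_table = pd.read_csv(config.design, sep="\t", comment="#")
            design = dict(zip(design_table["run"], design_table["group"]))
            log_matrix = equalize_medians(log2_transform(raw))
            imputed, flagged = impute_censored(log_matrix)
            if flagged:
                logger.warning("%d proteins left unimputed", len(flagged))
            run_summaries = summarize_runs(imputed)
            results = differential_test(
                run_summaries,
                design,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
                fc_scale=config.fc_scale,
            )
            diff = pd.DataFrame([dataclasses.asdict(r) for r in results])
            if not diff.empty:
                diff["neg_log10_adj_p"] = -np.log10(diff["adj_p"])
            emit("run_summaries", "run_summaries.tsv", run_summaries, index=True)
            emit("differential", "differential.tsv", diff)

            stage = "prioritize"
            groups = sorted(set(design.values()))
            group_means = pd.DataFrame(
                {
                    g: run_summaries[
                        [r for r in run_summaries.columns if design.get(r) == g]
                    ].mean(axis=1)
                    for g in groups
                }
            )
            linear = (2.0 ** group_means).fillna(0.0)
            profiles = [
                AbundanceProfile(str(acc), tuple(row), tuple(groups))
                for acc, row in linear.iterrows()
            ]
            spc_scores = {a: s.spc_score for a, s in surface.items()}
            ranked = score_markers(profiles, spc_scores, mode="omni")
            emit(
                "markers",
                "markers.tsv",
                pd.DataFrame([dataclasses.asdict(m) for m in ranked]),
            )

            stage = "compare"
            presence = pd.DataFrame(
                {
                    g: raw[
                        [r for r in raw.columns if design.get(r) == g]
                    ].notna().any(axis=1)
                    for g in groups
                }
            ).groupby(level=0).any()
            report = exclusive_intersections(presence)
            emit(
                "intersections",
                "intersections.tsv",
                pd.DataFrame(
                    [
                        {"datasets": "&".join(combo), "count": count}
                        for combo, count, _acc in report.cells
                    ],
                    columns=["datasets", "count"],
                ),
            )

        stage = "config"
        config_path = out_dir / "effective_config.yaml"
        config.to_yaml(config_path)
        outputs["config"] = config_path
    except PipelineError:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage}: {exc}") from exc
    return outputs
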