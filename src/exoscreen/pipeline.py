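"""End-to-end orchestration of the screen analysis.

``run_all`` chains every stage — growth classification, ion annotation,
LOD computation, normalization, consumption calling, exudate ranking,
pathway scoring and PCA — on a directory of TSV inputs, writes all
stage outputs plus a machine-readable summary, and logs parameters and
input hashes to a run manifest.  Identical config yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation as ann
from . import exometabolome as exo
from . import growth as gr
from . import io as eio
from . import multivariate as mv
from . import pathways as pw
from .errors import ExoscreenError, ValidationError

log = logging.getLogger("exoscreen")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths to all inputs plus every tunable of the pipeline."""

    design: str
    growth: str
    features: str
    samples: str
    masses: str
    out_dir: str
    pathways: str | None = None
    alpha: float = 0.05
    mixotrophy_threshold: float = 0.10
    ppm_tolerance: float = 10.0
    produced_min: float = 0.0
    no_growth_od: float = 0.05
    day_final: float = 10.0
    exp_window: tuple[float, float] = (0.0, 4.0)
    pca_components: int = 5
    fdr: bool = False
    pathway_denominator: str = "distinct"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 <= self.mixotrophy_threshold <= 1:
            raise ValidationError("mixotrophy_threshold must be in [0, 1]")
        if self.ppm_tolerance <= 0:
            raise ValidationError("ppm_tolerance must be positive")
        if self.no_growth_od < 0:
            raise ValidationError("no_growth_od must be >= 0")
        if self.pca_components < 1:
            raise ValidationError("pca_components must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValidationError("config must be a mapping", file=str(path))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                f"unknown config key(s): {sorted(unknown)}", file=str(path))
        if "exp_window" in data:
            data["exp_window"] = tuple(data["exp_window"])
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis chain; returns the summary dict.

    Writes effects.tsv, annotations.tsv, lod.tsv, norm.tsv,
    norm_flags.tsv, consumption.tsv, exudate_ranks.tsv,
    pathway_scores.tsv (if a pathway table is configured),
    pca_scores.tsv, pca_loadings.tsv, summary.json and manifest.json
    into ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": dataclasses.asdict(config), "inputs": {},
                "stages": []}

    def stage(name, **info):
        log.info("stage %s %s", name, info)
        manifest["stages"].append({"stage": name, **info})

    try:
        inputs = {"design": config.design, "growth": config.growth,
                  "features": config.features, "samples": config.samples,
                  "masses": config.masses}
        if config.pathways:
            inputs["pathways"] = config.pathways
        for k, p in inputs.items():
            manifest["inputs"][k] = {"path": str(p), "sha256": _sha256(p)}

        design = eio.read_design(config.design)
        curves = eio.read_growth(config.growth)
        features = eio.read_feature_matrix(config.features, config.samples)
        masses = eio.read_masses(config.masses)
        stage("load", n_conditions=design.n_conditions,
              n_ions=features.n_ions, n_samples=len(features.samples))

        summaries = gr.summarize_growth(curves, day_final=config.day_final,
                                        exp_window=config.exp_window)
        effects = gr.classify_growth(
            summaries, design.control_id, alpha=config.alpha,
            no_growth_threshold_od=config.no_growth_od, fdr=config.fdr)
        effects.to_csv(out / "effects.tsv", sep="\t", index=False,
                       float_format="%.6g")
        stage("growth", n_classified=len(effects))

        annotations = ann.annotate_ions(features.ions, masses,
                                        tol_ppm=config.ppm_tolerance)
        ann.write_annotations(annotations, out / "annotations.tsv")
        met_ion = ann.metabolite_ion_map(annotations, features.intensities)
        stage("annotate",
              n_annotated=int((annotations["label"] != "").sum()),
              n_metabolites=len(met_ion))

        lod = exo.compute_lod(features, met_ion)
        lod.reset_index().to_csv(out / "lod.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        norm = exo.normalize(features, met_ion, lod, design)
        eio.write_normalized(norm, out / "norm.tsv", out / "norm_flags.tsv")
        stage("normalize", n_metabolites=len(norm.values))

        calls = exo.consumption(features, met_ion, design,
                                threshold=config.mixotrophy_threshold,
                                alpha=config.alpha)
        calls.to_csv(out / "consumption.tsv", sep="\t", index=False,
                     float_format="%.6g")
        mixo = exo.mixotrophic_metabolites(calls)
        stage("consumption", n_calls=len(calls), n_mixotrophic=len(mixo))

        ranks = exo.rank_exudates(norm)
        ranks.to_csv(out / "exudate_ranks.tsv", sep="\t", index=False,
                     float_format="%.6g")
        stage("rank", n_metabolites=len(ranks))

        if config.pathways:
            db = eio.read_pathways(config.pathways)
            scores = pw.score_pathways(norm, db,
                                       produced_min=config.produced_min,
                                       denominator=config.pathway_denominator)
            scores.to_csv(out / "pathway_scores.tsv", sep="\t", index=False,
                          float_format="%.6g")
            stage("pathways", n_rows=len(scores))

        no_growth = set(effects.loc[
            effects["effect_class"] == "complete_inhibition", "condition_id"])
        n_comp = min(config.pca_components,
                     norm.values.shape[0],
                     norm.values.shape[1] - len(no_growth))
        res = mv.pca(norm, n_components=n_comp,
                     exclude_conditions=no_growth)
        res.scores.rename_axis("condition_id").reset_index().to_csv(
            out / "pca_scores.tsv", sep="\t", index=False,
            float_format="%.10g")
        res.loadings.rename_axis("metabolite_id").reset_index().to_csv(
            out / "pca_loadings.tsv", sep="\t", index=False,
            float_format="%.10g")
        stage("pca", n_components=res.n_components,
              explained=[round(float(v), 6)
                         for v in res.explained_variance_fraction])

        class_counts = effects["effect_class"].value_counts().to_dict()
        summary = {
            "n_conditions": design.n_conditions,
            "n_supplemented": len(design.supplemented),
            "n_enhanced": int(class_counts.get("enhanced", 0)),
            "n_inhibited": int(class_counts.get("inhibited", 0))
            + int(class_counts.get("complete_inhibition", 0)),
            "n_no_growth": int(class_counts.get("complete_inhibition", 0)),
            "n_none": int(class_counts.get("none", 0)),
            "n_measurable_metabolites": len(design.measurable_metabolites()),
            "mixotrophic_metabolites": mixo,
            "n_mixotrophic": len(mixo),
            "top10_exudates": list(ranks["metabolite_id"].head(10)),
            "pca_explained_variance_fraction": [
                float(v) for v in res.explained_variance_fraction],
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return summary
    except ExoscreenError:
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        done = manifest["stages"][-1]["stage"] if manifest["stages"] else "load"
        raise ExoscreenError(
            f"pipeline failed after stage {done!r}: {exc}") from exc
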