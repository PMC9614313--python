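"""End-to-end experiment orchestration.

``run_experiment`` wires the full framework together on synthetic data:
simulate an age-structured cohort plus atlas templates, build and label a
statistical atlas, segment every test subject with single-atlas (per
template) and multi-atlas fusion plus a density-threshold baseline, score
everything against the generator's ground truth (including motion-stratified
comparison), and quantify tissue CSA/density from the fused segmentations.
The run is fully reproducible: one base seed expands into per-stage seeds
through a fixed counter scheme, and the report contains no wall-clock state.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .atlas import AtlasSet, build_statistical_atlas
from .core_raster import TISSUE_NAMES, write_image, write_labels
from .evaluation import (
    PerformanceRecord,
    motion_stratified_report,
    overlap_metrics,
    records_to_frame,
)
from .fusion import (
    segment_multi_atlas,
    segment_single_atlas,
    segment_threshold,
)
from .phantom import apply_motion_artifact, generate_cohort, site_tissues
from .quantification import quantify_subject
from .registration import RegistrationConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_experiment", "stage_seed"]


def stage_seed(base: int, counter: int) -> int:
    """Per-stage seed: ``(base * 1000 + counter) mod 2^31`` (documented
    counter scheme; counters are fixed per pipeline stage)."""
    return (int(base) * 1000 + int(counter)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Configuration of the demonstration experiment."""

    seed: int = 0
    site: int = 66
    n_subjects: int = 10
    n_templates: int = 3
    image_size: int = 64
    spacing: float = 0.5
    engine: str = "sdd"
    fusion: str = "staple"
    atlas_iterations: int = 3
    include_statistical: bool = True
    geometry_jitter: float = 0.03
    deformation_amplitude: float = 1.5
    grades: tuple[int, ...] | None = None   # None: round-robin 1..5
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        reg = data.pop("registration", None)
        cfg = cls(**data)
        if reg:
            cfg.registration = RegistrationConfig(**reg)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["grades"] is not None:
            d["grades"] = list(d["grades"])
        return d


def _method_records(subject, pred, tissues, method) -> list[PerformanceRecord]:
    out = []
    for t in tissues:
        dsc, tpr, pr = overlap_metrics(pred, subject.labels, t)
        out.append(PerformanceRecord(
            subject_id=subject.subject_id, tissue=t, dsc=dsc, tpr=tpr, pr=pr,
            motion_grade=subject.motion_grade, method=method))
    return out


def run_experiment(config: PipelineConfig | None = None) -> dict:
    """Run the full simulate -> atlas -> segment -> evaluate -> quantify
    pipeline and return a JSON-serializable report.

    Any stage failure raises with a stage-tagged message.  If
    ``config.output_dir`` is set, the report, record tables and atlas files
    are written there and listed in the report's manifest.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    stage = "simulate"
    try:
        templates = generate_cohort(
            n=config.n_templates, site=config.site,
            seed=stage_seed(config.seed, 1),
            image_size=config.image_size, spacing=config.spacing,
            geometry_jitter=config.geometry_jitter,
            with_motion=False,
            deformation_amplitude=config.deformation_amplitude)
        subjects = generate_cohort(
            n=config.n_subjects, site=config.site,
            seed=stage_seed(config.seed, 2),
            image_size=config.image_size, spacing=config.spacing,
            geometry_jitter=config.geometry_jitter,
            with_motion=False,
            deformation_amplitude=config.deformation_amplitude)
        grades = (list(config.grades) if config.grades is not None
                  else [(i % 5) + 1 for i in range(config.n_subjects)])
        if len(grades) != config.n_subjects:
            raise ValueError("grades list must match n_subjects")
        for i, (rec, grade) in enumerate(zip(subjects, grades)):
            rec.motion_grade = int(grade)
            if grade > 1:
                rec.image = apply_motion_artifact(
                    rec.image, rec.labels, grade,
                    seed=stage_seed(config.seed, 100 + i))

        stage = "build-atlas"
        stat_atlas, provenance = build_statistical_atlas(
            [t.image for t in templates], K=config.atlas_iterations,
            reference_index=0, config=config.registration, engine=config.engine)
        # Label the atlas by propagating the reference template's ground
        # truth through atlas-space registration (automated stand-in for
        # expert labeling of the group template).
        ref = templates[0]
        stat_labels = segment_single_atlas(
            stat_atlas, ref.image, ref.labels, config.engine, config.registration)
        atlas_set = AtlasSet(
            templates=[(t.image, t.labels) for t in templates[1:]],
            statistical_atlas=stat_atlas,
            statistical_atlas_labels=stat_labels,
            provenance=provenance)
        rater_names = [f"sais_template{i + 1}" for i in range(len(templates) - 1)]
        if config.include_statistical:
            rater_names.append("sais_stat")

        stage = "segment"
        tissues = sorted(site_tissues(config.site))
        records: list[PerformanceRecord] = []
        staple_params = []
        fused_maps = {}
        for rec in subjects:
            rep: dict = {}
            fused = segment_multi_atlas(
                rec.image, atlas_set, engine=config.engine,
                config=config.registration, fusion=config.fusion,
                include_statistical=config.include_statistical, report=rep)
            fused_maps[rec.subject_id] = fused
            records += _method_records(rec, fused, tissues, "mais")
            for name, per_map in zip(rater_names, rep.get("per_atlas", [])):
                records += _method_records(rec, per_map, tissues, name)
            if "p" in rep:
                staple_params.append({
                    "subject_id": rec.subject_id,
                    "p": rep["p"].tolist(), "q": rep["q"].tolist(),
                    "em_iterations": rep.get("em_iterations"),
                    "classes": rep["staple"].classes.tolist(),
                })
            baseline = segment_threshold(rec.image)
            records += _method_records(rec, baseline, tissues, "threshold")

        stage = "evaluate"
        records_df = records_to_frame(records)
        motion_df = motion_stratified_report(records_df)

        stage = "quantify"
        quant_rows = []
        for rec in subjects:
            q = quantify_subject(rec.image, fused_maps[rec.subject_id],
                                 rec.subject_id, rec.age, rec.sex, rec.site)
            quant_rows.append(q.to_row())
        quant_df = pd.DataFrame(quant_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    elapsed = time.perf_counter() - t0
    logger.info("experiment finished in %.1f s", elapsed)

    mean_dsc = records_df.groupby(["method", "tissue"])["dsc"].mean()
    report = {
        "config": config.to_dict(),
        "tissues": {int(t): TISSUE_NAMES[t] for t in tissues},
        "mean_dsc": {
            method: {int(t): float(v) for (m2, t), v in mean_dsc.items()
                     if m2 == method}
            for method in records_df["method"].unique()
        },
        "records": records_df.to_dict(orient="records"),
        "motion_report": motion_df.to_dict(orient="records"),
        "staple": staple_params,
        "atlas_provenance": provenance,
        "quantification": quant_df.to_dict(orient="records"),
        "manifest": [],
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_df.to_csv(out / "performance_records.csv", index=False)
        motion_df.to_csv(out / "motion_report.csv", index=False)
        quant_df.to_csv(out / "quantification.csv", index=False)
        write_image(stat_atlas, out / "statistical_atlas.nii.gz")
        write_labels(stat_labels, out / "statistical_atlas_labels.nii.gz")
        manifest = ["performance_records.csv", "motion_report.csv",
                    "quantification.csv", "statistical_atlas.nii.gz",
                    "statistical_atlas_labels.nii.gz"]
        for sid, fused in fused_maps.items():
            name = f"{sid}_mais_labels.nii.gz"
            write_labels(fused, out / name)
            manifest.append(name)
        report["manifest"] = manifest + ["report.json"]
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
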