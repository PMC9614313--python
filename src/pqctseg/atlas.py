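"""Statistical atlas construction by iterative group averaging.

A statistical atlas is a group-average template: all subjects are mapped to
a common reference space and averaged, and the average itself becomes the
reference for subsequent nonlinear refinement passes.  Iteration 1 uses
affine registration to a chosen reference subject; iteration 2 onwards uses
nonlinear registration to the current average only.  The per-iteration
mean-squared change between successive templates is recorded in the
provenance (it should decay once nonlinear refinement starts, which is
logged, not enforced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_raster import (
    AffineTransform,
    DisplacementField,
    LabelMap2D,
    Raster2D,
    warp_image,
    warp_labels,
)
from .registration import (
    RegistrationConfig,
    register_affine,
    register_ffd,
    register_sdd,
)

logger = logging.getLogger(__name__)

__all__ = ["AtlasSet", "build_statistical_atlas", "label_statistical_atlas"]


@dataclass
class AtlasSet:
    """Template images + label maps plus one statistical atlas."""

    templates: list[tuple[Raster2D, LabelMap2D]]
    statistical_atlas: Raster2D | None = None
    statistical_atlas_labels: LabelMap2D | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.templates and self.statistical_atlas is None:
            raise ValueError("an atlas set needs at least one template or atlas")
        for img, lab in self.templates:
            if not img.same_grid_as(lab):
                raise ValueError("template image and label map grids differ")

    def raters(self, include_statistical: bool = True
               ) -> list[tuple[Raster2D, LabelMap2D]]:
        out = list(self.templates)
        if include_statistical and self.statistical_atlas is not None:
            out.append((self.statistical_atlas, self.statistical_atlas_labels))
        return out


def _register_nonlinear(fixed: Raster2D, moving: Raster2D, engine: str,
                        config: RegistrationConfig):
    if engine == "sdd":
        tau, _ = register_sdd(fixed, moving, config)
        return tau
    if engine == "ffd":
        return register_ffd(fixed, moving, config)
    raise ValueError(f"unknown engine {engine!r}; use 'ffd' or 'sdd'")


def build_statistical_atlas(
    subjects: list[Raster2D],
    K: int = 5,
    reference_index: int = 0,
    config: RegistrationConfig | None = None,
    engine: str = "sdd",
) -> tuple[Raster2D, dict]:
    """Iteratively average subject scans into a statistical atlas.

    Iteration 1 affinely registers every subject to ``subjects[reference_index]``
    and averages the warped intensities; iterations 2..K nonlinearly register
    every subject to the current average and re-average.  Pixels a subject
    maps outside its field of view are excluded from that pixel's mean.
    A subject whose registration raises is excluded with a warning; at least
    two survivors are required (a single-subject input trivially returns it).

    Returns the final average and a provenance dict with the build
    parameters and the per-iteration mean-squared template change.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not subjects:
        raise ValueError("need at least one subject")
    config = config or RegistrationConfig()
    provenance: dict = {
        "n_subjects": len(subjects), "K": K,
        "reference_index": reference_index, "engine": engine,
        "template_change": [], "excluded": [],
    }
    if len(subjects) == 1:
        atlas = Raster2D(subjects[0].values.copy(), subjects[0].spacing,
                         subjects[0].origin)
        return atlas, provenance

    reference = subjects[reference_index]
    affines: list[AffineTransform] = []
    atlas = reference
    for iteration in range(1, K + 1):
        acc = np.zeros(reference.shape, dtype=np.float64)
        weight = np.zeros(reference.shape, dtype=np.float64)
        survivors = 0
        for idx, subject in enumerate(subjects):
            try:
                if iteration == 1:
                    mu = register_affine(atlas, subject, config)
                    affines.append(mu)
                    warped = warp_image(subject, mu, out_grid=atlas)
                    mask_img = Raster2D(np.ones(subject.shape), subject.spacing,
                                        subject.origin)
                    mask = warp_image(mask_img, mu, out_grid=atlas).values
                else:
                    moving = warp_image(subject, affines[idx], out_grid=atlas)
                    tau = _register_nonlinear(atlas, moving, engine, config)
                    warped = warp_image(moving, tau)
                    mask_img = Raster2D(np.ones(moving.shape), moving.spacing,
                                        moving.origin)
                    mask = warp_image(mask_img, tau).values
            except Exception as exc:  # registration failure: drop the subject
                logger.warning("excluding subject %d at iteration %d: %s",
                               idx, iteration, exc)
                if idx not in provenance["excluded"]:
                    provenance["excluded"].append(idx)
                continue
            inside = mask > 0.5
            acc[inside] += warped.values[inside]
            weight[inside] += 1.0
            survivors += 1
        if survivors < 2:
            raise RuntimeError("fewer than two subjects survived registration")
        new_values = np.where(weight > 0, acc / np.maximum(weight, 1.0), 0.0)
        change = float(np.mean((new_values - atlas.values) ** 2))
        provenance["template_change"].append(change)
        logger.info("atlas iteration %d: mean-squared template change %.4g",
                    iteration, change)
        atlas = Raster2D(new_values, reference.spacing, reference.origin)
    return atlas, provenance


def label_statistical_atlas(
    atlas: Raster2D,
    reference_labels: LabelMap2D,
    reference_to_atlas: AffineTransform | DisplacementField,
) -> LabelMap2D:
    """Propagate a labelled reference's tissue map onto the atlas.

    ``reference_to_atlas`` must map atlas-grid points into the reference
    image (pull-back convention).  Propagation is nearest-neighbour, so the
    output label set is a subset of the reference's.
    """
    if reference_to_atlas is None:
        raise ValueError("a reference-to-atlas transform is required")
    return warp_labels(reference_labels, reference_to_atlas, out_grid=atlas)
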