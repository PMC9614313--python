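"""Single-atlas segmentation, label propagation, and STAPLE fusion.

Single-atlas image segmentation (SAIS) registers one atlas to the subject
(affine, then deformable) and propagates the atlas labels through the
composed transform with nearest-neighbour interpolation.  Multi-atlas image
segmentation (MAIS) repeats this for several atlases and fuses the
propagated label maps — by default with STAPLE (simultaneous truth and
performance level estimation), an EM algorithm that jointly estimates the
consensus segmentation and each rater's per-class sensitivity ``p`` and
specificity ``q``.  A majority-vote fusion and a fixed-threshold
density-based baseline segmenter are provided for comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_raster import (
    AIR,
    CORTICAL,
    MUSCLE,
    SAT,
    TRABECULAR,
    LabelMap2D,
    Raster2D,
    compose_affine_field,
    warp_labels,
)
from .atlas import AtlasSet
from .registration import (
    RegistrationConfig,
    register_affine,
    register_ffd,
    register_sdd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StapleState",
    "segment_single_atlas",
    "staple_fuse",
    "majority_vote",
    "segment_multi_atlas",
    "segment_threshold",
    "DEFAULT_THRESHOLDS",
]


# ---------------------------------------------------------------------------
# Single-atlas segmentation
# ---------------------------------------------------------------------------

def segment_single_atlas(
    S: Raster2D,
    atlas: Raster2D,
    atlas_labels: LabelMap2D,
    engine: str = "sdd",
    config: RegistrationConfig | None = None,
    report: dict | None = None,
) -> LabelMap2D:
    """Segment a subject by warping one atlas onto it (SAIS).

    Affine registration of the atlas to the subject is followed by the
    chosen deformable engine; the atlas labels are propagated through the
    composed transform in a single nearest-neighbour resampling pass, so the
    output lives on the subject grid.  Registration warnings are attached to
    ``report``.
    """
    config = config or RegistrationConfig()
    if not atlas.same_grid_as(atlas_labels):
        raise ValueError("atlas image and label map must share a grid")
    warnings: list[str] = []
    rep_aff: dict = {}
    mu = register_affine(S, atlas, config, report=rep_aff)
    if rep_aff.get("warning"):
        warnings.append(rep_aff["warning"])
    from .core_raster import warp_image
    atlas_aligned = warp_image(atlas, mu, out_grid=S)

    rep_def: dict = {}
    if engine == "sdd":
        tau, _ = register_sdd(S, atlas_aligned, config, report=rep_def)
    elif engine == "ffd":
        tau = register_ffd(S, atlas_aligned, config, report=rep_def)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'ffd' or 'sdd'")
    if rep_def.get("warning"):
        warnings.append(rep_def["warning"])

    total = compose_affine_field(mu, tau)
    out = warp_labels(atlas_labels, total, out_grid=S)
    if report is not None:
        report["warnings"] = warnings
        report["affine"] = mu
        report["field"] = tau
    return out


# ---------------------------------------------------------------------------
# STAPLE
# ---------------------------------------------------------------------------

@dataclass
class StapleState:
    """Decision matrix and per-rater performance parameters for STAPLE.

    ``decisions`` is the N-pixel x K-rater matrix of label codes.  After
    fusion, ``p[k, l]`` / ``q[k, l]`` hold rater ``k``'s one-vs-rest
    sensitivity / specificity for class ``classes[l]``, ``posteriors`` the
    per-pixel class weights, and ``log_likelihood`` the (non-decreasing)
    observed-data log-likelihood trace.
    """

    decisions: np.ndarray
    shape: tuple[int, int]
    spacing: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)
    classes: np.ndarray | None = None
    priors: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    posteriors: np.ndarray | None = None
    log_likelihood: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions)
        if self.decisions.ndim != 2:
            raise ValueError("decisions must be (n_pixels, n_raters)")

    @classmethod
    def from_label_maps(cls, maps: list[LabelMap2D]) -> "StapleState":
        if len(maps) < 2:
            raise ValueError("STAPLE needs at least 2 raters")
        first = maps[0]
        for m in maps[1:]:
            if m.shape != first.shape:
                raise ValueError("all rater maps must share a grid")
        D = np.stack([m.labels.ravel() for m in maps], axis=1)
        return cls(D, first.shape, first.spacing, first.origin)


def staple_fuse(
    state: StapleState | list[LabelMap2D],
    tol: float = 1e-5,
    max_iter: int = 100,
    init_p: float = 0.9,
) -> tuple[LabelMap2D, np.ndarray, np.ndarray]:
    """Fuse K propagated label maps by STAPLE EM.

    Per-rater, per-class performance is modeled one-vs-rest: sensitivity
    ``p[k,l] = Pr(e_k = l | T = l)`` and specificity ``q[k,l] =
    Pr(e_k != l | T != l)``.  The E-step computes per-pixel class posteriors
    by Bayes' rule from the current sensitivities (a rater's miss
    probability is spread uniformly over the remaining classes) with class
    priors fixed at the observed vote frequencies; the M-step re-estimates
    ``p`` and ``q`` in closed form.  Iteration stops when
    ``max(|dp|, |dq|) < tol`` or at ``max_iter``.  The fused map is the
    per-pixel posterior arg-max with ties broken toward the lowest label
    code.  A rater whose decision map is constant has its parameters
    clamped to [0.01, 0.99] to avoid a degenerate likelihood.

    Returns ``(fused_labels, p, q)``; the full state (posteriors, priors,
    log-likelihood trace) is available when a :class:`StapleState` is
    passed in.
    """
    if isinstance(state, list):
        state = StapleState.from_label_maps(state)
    D = state.decisions
    n_pixels, n_raters = D.shape
    if n_raters < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    classes = np.unique(D)
    if classes.size < 2:
        raise ValueError("STAPLE needs at least 2 distinct label codes")
    L = classes.size
    state.classes = classes

    # Vote indicator tensors, shape (n_pixels, n_raters, L)
    agree = (D[:, :, None] == classes[None, None, :])
    constant_raters = np.array([np.unique(D[:, k]).size == 1 for k in range(n_raters)])

    priors = agree.sum(axis=(0, 1)).astype(np.float64)
    priors /= priors.sum()
    state.priors = priors

    p = np.full((n_raters, L), init_p)
    q = np.full((n_raters, L), init_p)
    eps = 1e-12
    prev_ll = -np.inf
    state.log_likelihood = []

    for _ in range(max_iter):
        # E-step: log posterior over classes per pixel.
        pc = np.clip(p, eps, 1 - eps)
        log_like = np.where(agree, np.log(pc)[None, :, :],
                            np.log((1 - pc) / max(L - 1, 1))[None, :, :])
        logW = np.log(priors + eps)[None, :] + log_like.sum(axis=1)
        m = logW.max(axis=1, keepdims=True)
        W = np.exp(logW - m)
        norm = W.sum(axis=1, keepdims=True)
        W /= norm
        ll = float(np.sum(m.ravel() + np.log(norm.ravel())))
        if state.log_likelihood:
            # EM guarantee: the observed-data log-likelihood never decreases.
            assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), \
                "STAPLE log-likelihood decreased"
        state.log_likelihood.append(ll)
        prev_ll = ll

        # M-step: closed-form one-vs-rest sensitivities/specificities.
        Wl = W.sum(axis=0) + eps                      # (L,)
        notWl = n_pixels - W.sum(axis=0) + eps
        new_p = np.einsum("xl,xkl->kl", W, agree.astype(np.float64)) / Wl[None, :]
        new_q = np.einsum("xl,xkl->kl", 1.0 - W, (~agree).astype(np.float64)) / notWl[None, :]
        if constant_raters.any():
            new_p[constant_raters] = np.clip(new_p[constant_raters], 0.01, 0.99)
            new_q[constant_raters] = np.clip(new_q[constant_raters], 0.01, 0.99)
        delta = max(float(np.abs(new_p - p).max()), float(np.abs(new_q - q).max()))
        p, q = new_p, new_q
        if delta < tol:
            break

    state.p, state.q = p, q
    state.posteriors = W
    fused_idx = np.argmax(W, axis=1)  # argmax returns the first (lowest) class on ties
    fused = classes[fused_idx].reshape(state.shape)
    labels = LabelMap2D(fused, state.spacing, state.origin)
    return labels, p, q


def majority_vote(maps: list[LabelMap2D]) -> LabelMap2D:
    """Per-pixel modal label across raters; ties go to the lowest code."""
    if len(maps) < 2:
        raise ValueError("majority vote needs at least 2 raters")
    D = np.stack([m.labels.ravel() for m in maps], axis=1)
    classes = np.unique(D)
    counts = (D[:, :, None] == classes[None, None, :]).sum(axis=1)
    fused = classes[np.argmax(counts, axis=1)].reshape(maps[0].shape)
    return LabelMap2D(fused, maps[0].spacing, maps[0].origin)


# ---------------------------------------------------------------------------
# Multi-atlas segmentation
# ---------------------------------------------------------------------------

def segment_multi_atlas(
    S: Raster2D,
    atlases: AtlasSet,
    engine: str = "sdd",
    config: RegistrationConfig | None = None,
    fusion: str = "staple",
    include_statistical: bool = True,
    report: dict | None = None,
) -> LabelMap2D:
    """Multi-atlas segmentation: per-atlas SAIS, then label fusion (MAIS).

    Runs :func:`segment_single_atlas` for every rater in the atlas set (the
    statistical atlas included by default), builds the pixel x rater
    decision matrix and fuses it.  If fewer than two per-atlas segmentations
    succeed, the best-effort single result is returned with a warning.
    """
    raters = atlases.raters(include_statistical=include_statistical)
    if len(raters) < 2:
        raise ValueError("MAIS needs at least 2 atlases")
    per_atlas: list[LabelMap2D] = []
    warnings: list[str] = []
    for i, (img, lab) in enumerate(raters):
        try:
            rep: dict = {}
            per_atlas.append(segment_single_atlas(S, img, lab, engine, config, rep))
            warnings.extend(f"atlas {i}: {w}" for w in rep.get("warnings", []))
        except Exception as exc:
            warnings.append(f"atlas {i} failed: {exc}")
            logger.warning("atlas %d segmentation failed: %s", i, exc)
    if len(per_atlas) < 2:
        if not per_atlas:
            raise RuntimeError("all per-atlas segmentations failed")
        warnings.append("fewer than 2 raters succeeded; returning single result")
        if report is not None:
            report.update({"per_atlas": per_atlas, "warnings": warnings})
        return per_atlas[0]

    if fusion == "staple":
        staple_state = StapleState.from_label_maps(per_atlas)
        fused, p, q = staple_fuse(staple_state)
        if report is not None:
            report.update({
                "per_atlas": per_atlas, "warnings": warnings,
                "staple": staple_state, "p": p, "q": q,
                "em_iterations": len(staple_state.log_likelihood),
            })
        return fused
    if fusion == "majority":
        fused = majority_vote(per_atlas)
        if report is not None:
            report.update({"per_atlas": per_atlas, "warnings": warnings})
        return fused
    raise ValueError(f"unknown fusion {fusion!r}; use 'staple' or 'majority'")


# ---------------------------------------------------------------------------
# Fixed-threshold density baseline
# ---------------------------------------------------------------------------

# Density intervals (calibrated units) chosen between the phantom tissue
# modes; a pure intensity classifier with no spatial model, representative of
# conventional density-threshold segmentation.
DEFAULT_THRESHOLDS: dict[int, tuple[float, float]] = {
    SAT: (20.0, 65.0),
    MUSCLE: (65.0, 190.0),
    TRABECULAR: (190.0, 700.0),
    CORTICAL: (700.0, np.inf),
}


def segment_threshold(
    image: Raster2D,
    thresholds: dict[int, tuple[float, float]] | None = None,
) -> LabelMap2D:
    """Density-threshold baseline: classify each pixel by fixed intensity
    intervals.  No spatial regularization — deliberately fragile to noise
    and motion streaks."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    labels = np.full(image.shape, AIR, dtype=np.uint8)
    for code, (lo, hi) in thresholds.items():
        labels[(image.values >= lo) & (image.values < hi)] = code
    return LabelMap2D(labels, image.spacing, image.origin)
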