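"""End-to-end runs: the two-stage register / measure workflow.

``run_register`` chains preprocess -> foreground -> segment3d ->
morphometry.apply_criteria; ``run_measure`` applies scripted edits and
finishes the morphometry (neighbors, corrected diameters).  Both are
pure library entry points used by the CLI and by tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import __version__
from .foreground import (
    HoleFillParams,
    apply_roi_mask,
    fill_holes_bounded,
    interpolate_roi,
    threshold_mean,
)
from .morphometry import (
    FilterCriteria,
    MeasureConfig,
    apply_criteria,
    apply_edit_list,
    mean_and_corrected_diameter,
    measure_all,
    nearest_neighbor_distances,
)
from .preprocess import PreprocessParams, run_preprocess
from .segment3d import SegmentParams, run_segmentation

__all__ = ["RunConfig", "PRESETS", "run_register", "run_measure", "make_composite"]

# Organism presets for the exclusion criteria (volume in voxels at the
# 1 nm/px working scale; sphericity/elongation shared by all presets).
PRESETS = {
    "zebrafish_30k": {"min_volume_vx": 6500.0, "min_sphericity": 0.5,
                      "max_elongation": 2.0},
    "zebrafish_20k": {"min_volume_vx": 5000.0, "min_sphericity": 0.5,
                      "max_elongation": 2.0},
    "celegans": {"min_volume_vx": 3000.0, "min_sphericity": 0.5,
                 "max_elongation": 2.0},
}


@dataclass
class RunConfig:
    """Union of all stage parameter blocks plus run-level options.

    ``threshold_polarity`` defaults to "bright": the pipeline registers
    the membrane-bounded lumina (brighter than the granular field), so
    the reported diameters track the inner vesicle diameter; the dark
    membrane mesh is eliminated by the large-component filter.
    """

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    holes: HoleFillParams = field(default_factory=HoleFillParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    threshold_polarity: str = "bright"
    seed: int = 0

    @classmethod
    def from_options(cls, preset=None, **overrides):
        """Build a config from an optional organism preset plus flat
        key=value overrides (explicit values win over the preset)."""
        crit_kw = dict(PRESETS[preset]) if preset else {}
        groups = {
            "preprocess": PreprocessParams,
            "holes": HoleFillParams,
            "segment": SegmentParams,
            "measure": MeasureConfig,
        }
        kwargs = {}
        top = {}
        for key, value in overrides.items():
            if value is None:
                continue
            top[key] = value
        for name, cls_ in groups.items():
            fields = cls_.__dataclass_fields__
            kw = {k: top.pop(k) for k in list(top) if k in fields}
            kwargs[name] = cls_(**kw)
        crit_fields = FilterCriteria.__dataclass_fields__
        crit_kw.update({k: top.pop(k) for k in list(top) if k in crit_fields})
        kwargs["criteria"] = FilterCriteria(**crit_kw)
        for k in ("threshold_polarity", "seed"):
            if k in top:
                kwargs[k] = top.pop(k)
        if top:
            raise ValueError(f"unknown config keys: {sorted(top)}")
        return cls(**kwargs)

    def to_manifest(self, **extra):
        import scipy
        import skimage

        manifest = {
            "config": {
                "preprocess": asdict(self.preprocess),
                "holes": asdict(self.holes),
                "segment": asdict(self.segment),
                "criteria": asdict(self.criteria),
                "measure": asdict(self.measure),
                "threshold_polarity": self.threshold_polarity,
                "seed": self.seed,
            },
            "versions": {
                "vesel": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-image": skimage.__version__,
            },
        }
        manifest.update(extra)
        return manifest


def run_register(stack, roi_first, roi_last, config=None, log=None):
    """Detection stage.  Returns (labels, records, preprocessed stack).

    Records carry geometry and shape measures; neighbor distances and
    corrected diameters are left for the measurement stage.
    """
    config = config or RunConfig()
    say = log or (lambda msg: None)

    pre = run_preprocess(stack, config.preprocess)
    say(f"preprocessed: shape={pre.shape} px={pre.px_size_xy} nm")

    binary = threshold_mean(pre, polarity=config.threshold_polarity)
    say(f"threshold({config.threshold_polarity}): "
        f"{int(binary.mask.sum())} foreground voxels")

    scale = stack.px_size_xy / pre.px_size_xy
    rois = interpolate_roi(
        _scale_roi(roi_first, scale), _scale_roi(roi_last, scale), pre.shape[0]
    )
    binary = apply_roi_mask(binary, rois)
    say(f"roi mask: {int(binary.mask.sum())} foreground voxels")

    binary = fill_holes_bounded(binary, config.holes)
    say(f"hole fill: {int(binary.mask.sum())} foreground voxels")

    labels = run_segmentation(binary, config.segment)
    n_candidates = len(labels.ids())
    say(f"segmentation: {n_candidates} candidates")

    records = measure_all(labels)
    labels, records = apply_criteria(records, labels, config.criteria)
    say(f"criteria: kept {len(records)} of {n_candidates}")
    for rec in records:
        mean_and_corrected_diameter(rec, config.measure)
    return labels, records, pre


def _scale_roi(roi, scale):
    if abs(scale - 1.0) < 1e-12:
        return roi
    from .io_formats import PolygonRoi

    return PolygonRoi(roi.slice_index, roi.vertices * scale)


def run_measure(labels, config=None, edits=None, log=None):
    """Measurement stage: apply edits, re-measure, set neighbor
    distances and corrected diameters.  Returns (labels, records)."""
    config = config or RunConfig()
    say = log or (lambda msg: None)
    records = measure_all(labels)
    if edits:
        labels, records = apply_edit_list(labels, records, edits)
        say(f"edits applied: {len(edits)}, {len(records)} labels remain")
    for rec in records:
        mean_and_corrected_diameter(rec, config.measure)
    nearest_neighbor_distances(records, config.measure)
    return labels, records


def make_composite(stack, labels):
    """Original stack with one-voxel label contours burned in at the
    stack maximum intensity (the proof-reading overlay)."""
    out = stack.voxels.astype(np.float32).copy()
    lab = labels.labels
    interior = ndi.grey_erosion(lab, footprint=np.ones((1, 3, 3)))
    contours = (lab > 0) & (interior != lab)
    out[contours] = out.max()
    return stack.with_voxels(out)


def write_manifest(path, manifest):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path):
    with open(path) as fh:
        return json.load(fh)
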