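"""End-to-end detection pipeline and its configuration.

Order of stages: superpixel segmentation at each scale -> features ->
appearance graph and geodesic distances -> boundary conductivity ->
dictionary refinement -> dense and sparse reconstruction errors ->
within-cluster propagation -> multiscale pixel lifting -> object-biased
Gaussian -> Bayesian fusion -> thresholding -> mask clean-up -> optional
external refiner.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from bgsal import abstraction, bgdict, mask as mask_mod, propagate, reconstruct
from bgsal.errors import StageError
from bgsal.mask import BinaryMask, Refiner

__all__ = ["PipelineConfig", "DetectionResult", "detect"]

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (50, 100, 150, 200, 250, 300, 350, 400)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the detection pipeline, serializable to YAML."""

    scales: tuple[int, ...] = DEFAULT_SCALES
    compactness: float = 10.0
    feature_subset: str = "lab"  # appearance distance on Lab only or "full"
    sigma_bc: float = 10.0  # bandwidth of the geodesic affinity
    K: float = 4.0  # dictionary threshold strength
    min_dict_atoms: int = bgdict.MIN_DICT_ATOMS
    refine: bool = True  # False keeps the whole border dictionary
    lam: float = 0.01  # L1 penalty of the sparse encoder
    explained_fraction: float = 0.95
    n_clusters: int = 8
    nu: float = 0.5
    sigma_f: float = 10.0
    seed: int = 0
    sigma_x: float | None = None  # object-bias widths; None = W/4, H/4
    sigma_y: float | None = None
    bayes_bins: int = 64
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.5

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["scales"] = list(self.scales)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "scales" in data:
            data["scales"] = tuple(int(s) for s in data["scales"])
        return cls(**data)


@dataclass
class DetectionResult:
    saliency_map: np.ndarray
    initial_mask: BinaryMask
    refined_mask: BinaryMask
    intermediates: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, stage_name: str):
            self.name = stage_name
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                if isinstance(exc, StageError):
                    return False
                raise StageError(self.name, exc) from exc
            logger.debug("stage %-22s %6.3f s", self.name, dt)
            return False

    return _Ctx(name)


def detect(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    refiner: Refiner | None = None,
    keep_intermediates: bool = False,
) -> DetectionResult:
    """Run the full salient-object-detection pipeline on one RGB image."""
    config = config or PipelineConfig()
    h, w = np.asarray(image).shape[:2]
    n_pixels = h * w

    per_scale_maps = []
    per_scale_features = []
    dense_per_scale = []
    sparse_per_scale = []
    prop_cfg = propagate.PropagationConfig(
        n_clusters=config.n_clusters,
        nu=config.nu,
        sigma_f=config.sigma_f,
        seed=config.seed,
    )
    sparse_cfg = reconstruct.SparseConfig(lam=config.lam)

    for scale_id, n_segments in enumerate(config.scales):
        n_segments = min(n_segments, max(n_pixels // 16, 4))
        with _stage(f"segment[{scale_id}]"):
            spmap = abstraction.segment_superpixels(
                image,
                n_segments=n_segments,
                compactness=config.compactness,
                seed=config.seed,
                scale_id=scale_id,
            )
        with _stage(f"features[{scale_id}]"):
            feats = abstraction.extract_features(image, spmap)
            boundary = abstraction.boundary_indices(spmap)
        with _stage(f"conductivity[{scale_id}]"):
            graph = bgdict.build_graph(spmap, feats, config.feature_subset)
            d_geo = bgdict.geodesic_distances(graph)
            fld = bgdict.boundary_conductivity(d_geo, boundary, config.sigma_bc)
            if config.refine:
                refined = bgdict.refine_dictionary(
                    fld, boundary, config.K, config.min_dict_atoms
                )
                atoms_idx = refined.kept_array
            else:
                atoms_idx = boundary.as_array()
        with _stage(f"reconstruction[{scale_id}]"):
            atoms = feats.F[atoms_idx]
            model = reconstruct.fit_dense_model(
                atoms, feats.f_bar, config.explained_fraction
            )
            dense = reconstruct.dense_errors(model, feats.F)
            sparse = reconstruct.sparse_errors(atoms, feats.F, sparse_cfg)
        with _stage(f"propagation[{scale_id}]"):
            dense = propagate.propagate_errors(feats, dense, prop_cfg)
            sparse = propagate.propagate_errors(feats, sparse, prop_cfg)
        per_scale_maps.append(spmap)
        per_scale_features.append(feats)
        dense_per_scale.append(dense)
        sparse_per_scale.append(sparse)

    with _stage("pixel_lift"):
        s_dense = propagate.pixel_errors_multiscale(
            dense_per_scale, per_scale_maps, per_scale_features, image, config.sigma_f
        )
        s_sparse = propagate.pixel_errors_multiscale(
            sparse_per_scale, per_scale_maps, per_scale_features, image, config.sigma_f
        )
    with _stage("object_bias"):
        s_dense = propagate.object_biased_reweight(
            s_dense, config.sigma_x, config.sigma_y
        )
        s_sparse = propagate.object_biased_reweight(
            s_sparse, config.sigma_x, config.sigma_y
        )
    with _stage("bayes_fusion"):
        saliency = propagate.bayesian_integrate(s_dense, s_sparse, config.bayes_bins)
    with _stage("mask"):
        initial = mask_mod.threshold_mask(
            saliency, config.threshold_method, config.fixed_threshold
        )
        initial = mask_mod.clean_mask(initial)
    with _stage("refiner"):
        refined_mask = mask_mod.apply_refiner(image, initial, refiner)

    intermediates = {}
    if keep_intermediates:
        intermediates = {
            "dense_map": s_dense,
            "sparse_map": s_sparse,
            "per_scale_maps": per_scale_maps,
            "per_scale_features": per_scale_features,
            "dense_errors": dense_per_scale,
            "sparse_errors": sparse_per_scale,
        }
    return DetectionResult(
        saliency_map=saliency,
        initial_mask=initial,
        refined_mask=refined_mask,
        intermediates=intermediates,
    )
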