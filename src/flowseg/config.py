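"""Pipeline configuration: one flat, serializable set of knobs.

A single config is frozen for a whole batch — the "one shot" mode — so the
initial self-tuning conditions (blur sigma, flow parameters, threshold
candidate grid, entropy window, seed) are identical for every image while
per-image threshold *selection* remains adaptive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace

from .exceptions import ContractError


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the pyramidal Farneback dense-flow estimator.

    ``window_size`` averages the normal equations over a neighborhood before
    solving (1 = per-pixel solve; the polynomial-expansion window of
    ``poly_n`` taps already aggregates a neighborhood). ``damping`` is the
    Tikhonov term of the displacement solve, expressed relative to the mean
    structure energy of the frame pair: weak-structure (background) pixels
    are pulled toward zero displacement instead of blowing up on a
    near-singular system.
    """

    pyr_scale: float = 0.5
    pyramid_levels: int = 3
    window_size: int = 1
    iterations: int = 3
    poly_n: int = 5
    poly_sigma: float = 1.1
    damping: float = 0.3


@dataclass(frozen=True)
class DeclumpParams:
    enabled: bool = False
    min_distance: int = 10
    footprint_radius: int = 7


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline.

    Attributes
    ----------
    blur_sigma : float
        Gaussian blur width in pixels used to synthesize the surrogate
        "second frame". Sub-pixel values are honoured via the
        pixel-integrated kernel (see :func:`flowseg.blur_flow.gaussian_blur`).
    threshold_grid_upper, threshold_grid_lower : tuple of float
        Percentile candidates (of the flow-magnitude distribution) for the
        cell and background thresholds; the self-tuner picks the pair
        maximizing the class entropy difference.
    entropy_window_radius : int
        Radius (px) of the disk window for local Shannon entropy.
    tuning_statistic : str
        'mean' (default) or 'median' class-entropy statistic for the
        self-tuning objective.
    max_training_pixels_per_class : int
        Class-balanced subsample cap before classifier fitting.
    use_empirical_priors : bool
        If True, class priors come from the pre-subsample label counts
        instead of the balanced (~0.5/0.5) post-subsample counts.
    """

    blur_sigma: float = 0.1
    flow: FlowParams = field(default_factory=FlowParams)
    entropy_window_radius: int = 4
    entropy_bins: int = 64
    magnitude_window: int = 15
    threshold_grid_upper: tuple[float, ...] = (80.0, 85.0, 90.0, 95.0)
    threshold_grid_lower: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    tuning_statistic: str = "mean"
    cv_folds: int = 10
    rng_seed: int = 0
    max_training_pixels_per_class: int = 50_000
    use_empirical_priors: bool = False
    min_object_area: int = 64
    fill_holes: bool = True
    declump: DeclumpParams = field(default_factory=DeclumpParams)

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ContractError("blur_sigma must be > 0")
        if self.cv_folds < 2:
            raise ContractError("cv_folds must be >= 2")
        for name in ("threshold_grid_upper", "threshold_grid_lower"):
            grid = getattr(self, name)
            if len(grid) == 0:
                raise ContractError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ContractError(f"{name} must be strictly increasing")
        if self.tuning_statistic not in ("mean", "median"):
            raise ContractError("tuning_statistic must be 'mean' or 'median'")
        if self.entropy_window_radius < 1:
            raise ContractError("entropy_window_radius must be >= 1")
        if self.magnitude_window < 1:
            raise ContractError("magnitude_window must be >= 1")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=int(seed))


_SCALARS = {
    "blur_sigma": float,
    "entropy_window_radius": int,
    "entropy_bins": int,
    "magnitude_window": int,
    "tuning_statistic": str,
    "cv_folds": int,
    "rng_seed": int,
    "max_training_pixels_per_class": int,
    "use_empirical_priors": lambda s: s.lower() in ("1", "true", "yes"),
    "min_object_area": int,
    "fill_holes": lambda s: s.lower() in ("1", "true", "yes"),
}
_FLOW_FIELDS = {
    "pyr_scale": float,
    "pyramid_levels": int,
    "window_size": int,
    "iterations": int,
    "poly_n": int,
    "poly_sigma": float,
    "damping": float,
}
_DECLUMP_FIELDS = {
    "enabled": lambda s: s.lower() in ("1", "true", "yes"),
    "min_distance": int,
    "footprint_radius": int,
}


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    """Serialize a config as flat ``key = value`` text."""
    flat: dict[str, object] = {}
    for key, value in asdict(config).items():
        if isinstance(value, dict):
            for sub, sval in value.items():
                flat[f"{key}.{sub}"] = sval
        elif isinstance(value, tuple):
            flat[key] = ",".join(str(v) for v in value)
        else:
            flat[key] = value
    with open(os.fspath(path), "w") as fh:
        for key, value in flat.items():
            fh.write(f"{key} = {value}\n")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse a flat ``key = value`` config file back into a PipelineConfig."""
    scalars: dict[str, object] = {}
    flow: dict[str, object] = {}
    declump: dict[str, object] = {}
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ContractError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("flow."):
                sub = key[5:]
                if sub not in _FLOW_FIELDS:
                    raise ContractError(f"{path}:{lineno}: unknown key {key}")
                flow[sub] = _FLOW_FIELDS[sub](value)
            elif key.startswith("declump."):
                sub = key[8:]
                if sub not in _DECLUMP_FIELDS:
                    raise ContractError(f"{path}:{lineno}: unknown key {key}")
                declump[sub] = _DECLUMP_FIELDS[sub](value)
            elif key in ("threshold_grid_upper", "threshold_grid_lower"):
                scalars[key] = tuple(float(v) for v in value.split(","))
            elif key in _SCALARS:
                scalars[key] = _SCALARS[key](value)
            else:
                raise ContractError(f"{path}:{lineno}: unknown key {key}")
    return PipelineConfig(
        flow=FlowParams(**flow), declump=DeclumpParams(**declump), **scalars
    )
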