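"""Synthetic fixtures with known ground truth for every pipeline stage.

The original micrographs and the trained network behind the published
workflow are not deposited anywhere, so controlled synthetic data defines
the test surface of this package:

* ``generate_blob_cloud`` — star-shaped C-alpha point clouds with a
  prescribed per-octant radial standard deviation, so the SRI computed
  from the cloud can be compared against the generating dispersion;
* ``generate_sierpinski`` — the Sierpinski carpet, whose box-counting
  dimension log 8 / log 3 ≈ 1.8928 is known analytically;
* ``generate_micrograph`` — grayscale noise images whose intensity-band
  occupancies are controlled, giving diverse ILMFD descriptors;
* ``generate_training_set`` — paired (ILMFD, SRI) samples under a known
  affine mapping plus optional Gaussian noise, for predictor recovery
  experiments.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .errors import ParameterError
from .structure_io import CalphaCloud, ResidueId

__all__ = [
    "CloudSpec",
    "TrainingSetSpec",
    "generate_blob_cloud",
    "generate_sierpinski",
    "generate_micrograph",
    "generate_training_set",
    "random_affine_mapping",
    "save_png",
]

# octant k (1..8) sign pattern under index = 1 + [x<0] + 2[y<0] + 4[z<0]
_OCTANT_SIGNS = np.array(
    [
        [+1, +1, +1],
        [-1, +1, +1],
        [+1, -1, +1],
        [-1, -1, +1],
        [+1, +1, -1],
        [-1, +1, -1],
        [+1, -1, -1],
        [-1, -1, -1],
    ],
    dtype=float,
)


@dataclass
class CloudSpec:
    """Recipe for a star-shaped cloud with controlled per-octant roughness.

    ``radial_mean`` must dominate the dispersions (> 3× the largest SD)
    so the cloud stays star-shaped and every generated point faces the
    centre from its own direction.
    """

    points_per_octant: int
    radial_mean: float
    radial_sd_per_octant: Sequence[float]
    seed: int
    anchor_frame: bool = True

    def __post_init__(self) -> None:
        self.radial_sd_per_octant = np.asarray(self.radial_sd_per_octant, dtype=float)
        if self.points_per_octant < 2:
            raise ParameterError("points_per_octant must be >= 2")
        if self.radial_sd_per_octant.shape != (8,) or np.any(
            self.radial_sd_per_octant < 0
        ):
            raise ParameterError("radial_sd_per_octant must be 8 non-negative values")
        if self.radial_mean <= 3 * self.radial_sd_per_octant.max():
            raise ParameterError("radial_mean must exceed 3 x max radial SD")


def generate_blob_cloud(spec: CloudSpec) -> CalphaCloud:
    """Generate a C-alpha cloud with known per-octant radial dispersion.

    For each octant k, ``points_per_octant`` directions are drawn
    uniformly within the octant and radii from
    Normal(radial_mean, radial_sd_per_octant[k]).

    With ``anchor_frame`` (default) two extra anchor residues are
    appended: one far out on +z (guaranteed farthest point) and one in
    the lamellar slab on +x. They pin the invariant frame to the
    generation frame, so the octant labelling of the computed SRI lines
    up with the per-octant dispersions that generated the cloud.
    """
    rng = np.random.default_rng(spec.seed)
    coords = []
    for k in range(8):
        # uniform directions within the octant: |gaussian| then signs
        d = np.abs(rng.normal(size=(spec.points_per_octant, 3)))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d *= _OCTANT_SIGNS[k]
        sd = spec.radial_sd_per_octant[k]
        radii = rng.normal(spec.radial_mean, sd, size=spec.points_per_octant)
        # truncate at +-4 sigma: keeps the SD essentially unchanged while
        # guaranteeing the frame anchors below stay the extreme points
        radii = np.clip(radii, spec.radial_mean - 4 * sd, spec.radial_mean + 4 * sd)
        radii = np.clip(radii, 0.1 * spec.radial_mean, None)
        coords.append(d * radii[:, None])
    pts = np.vstack(coords)
    if spec.anchor_frame:
        sd_max = spec.radial_sd_per_octant.max()
        r_z = spec.radial_mean + max(6.0 * sd_max, 0.05 * spec.radial_mean)
        r_x = spec.radial_mean + max(5.0 * sd_max, 0.025 * spec.radial_mean)
        anchors = np.array([[0.0, 0.0, r_z], [r_x, 0.0, 0.0]])
        pts = np.vstack([pts, anchors])
    residues = [
        ResidueId(chain_id="A", residue_number=i + 1, icode="", residue_name="GLY")
        for i in range(len(pts))
    ]
    return CalphaCloud(
        residues=residues, positions=pts, source_label=f"blob-seed{spec.seed}"
    )


def generate_sierpinski(depth: int) -> np.ndarray:
    """Sierpinski carpet of side 3**depth as a boolean image.

    True-pixel count is 8**depth; the box-counting dimension converges to
    log 8 / log 3 ≈ 1.8928.
    """
    if not 1 <= depth <= 6:
        raise ParameterError("depth must be between 1 and 6")
    carpet = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        n = carpet.shape[0]
        tiled = np.tile(carpet, (3, 3))
        tiled[n : 2 * n, n : 2 * n] = False
        carpet = tiled
    return carpet


def generate_micrograph(
    seed: int,
    shape: Tuple[int, int] = (90, 90),
    band_weights: Optional[Sequence[float]] = None,
    n_bands: int = 10,
) -> np.ndarray:
    """Grayscale noise image with controlled intensity-band occupancies.

    Every pixel is assigned to one of the ``n_bands`` equal-width
    intensity bands with probability proportional to ``band_weights``
    (default: uniform) and then given a uniform intensity within its
    band. Varying the weights varies the per-band occupancy and hence the
    per-band box-counting dimension, which is what the descriptor
    pipeline measures.
    """
    rng = np.random.default_rng(seed)
    if band_weights is None:
        w = np.ones(n_bands)
    else:
        w = np.asarray(band_weights, dtype=float)
        if w.shape != (n_bands,) or np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("band_weights must be n_bands non-negative values")
    p = w / w.sum()
    bands = rng.choice(n_bands, size=shape, p=p)
    width = 255.0 / n_bands
    lo = bands * width
    intensity = lo + rng.uniform(0.0, width, size=shape)
    return np.clip(np.floor(intensity), 0, 255).astype(np.uint8)


@dataclass
class TrainingSetSpec:
    """Recipe for a paired ILMFD → SRI training set under an affine map."""

    mapping_matrix: np.ndarray  # (8, 10)
    mapping_offset: np.ndarray  # (8,)
    n_samples: int
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        self.mapping_matrix = np.asarray(self.mapping_matrix, dtype=float)
        self.mapping_offset = np.asarray(self.mapping_offset, dtype=float)
        if self.mapping_matrix.shape != (8, 10) or self.mapping_offset.shape != (8,):
            raise ParameterError("mapping must be an 8x10 matrix plus 8 offsets")
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def random_affine_mapping(seed: int, scale: float = 2.0) -> Tuple[np.ndarray, np.ndarray]:
    """A reproducible random affine ILMFD → SRI mapping with non-negative
    outputs over the ILMFD sampling cube [0.5, 2]^10."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, scale / 10.0, size=(8, 10))
    b = rng.uniform(0.5, 1.5, size=8)
    return A, b


def generate_training_set(
    spec: TrainingSetSpec,
) -> list[Tuple[np.ndarray, np.ndarray]]:
    """Paired (ILMFD, SRI) samples: inputs uniform in [0.5, 2]^10, targets
    mapping(input) plus Normal(0, noise_sd) noise."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.5, 2.0, size=(spec.n_samples, 10))
    Y = X @ spec.mapping_matrix.T + spec.mapping_offset
    if spec.noise_sd > 0:
        Y = Y + rng.normal(0.0, spec.noise_sd, size=Y.shape)
    return [(X[i], Y[i]) for i in range(spec.n_samples)]


def save_png(array: np.ndarray, path) -> None:
    """Write a grayscale or boolean array as an 8-bit PNG."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8)).save(path)
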