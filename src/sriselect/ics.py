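"""The Invariant Coordinate System (ICS) of a C-alpha cloud.

The ICS is a protein-intrinsic right-handed frame built purely from the
C-alpha geometry, so that coordinates expressed in it are invariant under
rigid motion of the input:

1. the origin O is the centroid (mean) of all C-alpha positions;
2. the z-axis points from O toward the C-alpha farthest from O;
3. the x-axis points from O toward the projection onto the xy-plane of the
   C-alpha that is farthest from O among those lying within a lamellar
   slab of half-width 2 Å around the xy-plane;
4. the y-axis completes the right-handed frame, y = z × x.

Ties in the two argmax selections are broken by earliest file order, and a
near-tie (top two distances closer than 1e-6 Å) is logged because the
resulting frame is then numerically unstable. If the lamellar slab holds
no atom at all, its half-width is doubled until it does, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

from .errors import DegenerateGeometryError, EmptyStructureError
from .structure_io import CalphaCloud, ResidueId

__all__ = [
    "ICSFrame",
    "compute_origin",
    "compute_z_axis",
    "compute_x_axis",
    "build_frame",
    "transform_to_ics",
    "DEFAULT_LAMELLA_HALFWIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_LAMELLA_HALFWIDTH = 2.0  # Å; half of the 4 Å lamellar slab
_NEAR_TIE = 1e-6  # Å; log when the two leading distances are this close


@dataclass
class ICSFrame:
    """Origin plus right-handed orthonormal axes of the invariant frame."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray
    zmax_residue: Optional[ResidueId] = None
    xref_residue: Optional[ResidueId] = None
    lamella_halfwidth_used: float = DEFAULT_LAMELLA_HALFWIDTH

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis_x = np.asarray(self.axis_x, dtype=float)
        self.axis_y = np.asarray(self.axis_y, dtype=float)
        self.axis_z = np.asarray(self.axis_z, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """Row-stacked axes: multiplying (p - O) by this matrix transposed
        gives ICS coordinates."""
        return np.vstack([self.axis_x, self.axis_y, self.axis_z])

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=tol):
            raise DegenerateGeometryError("ICS axes not orthonormal")
        if not np.allclose(np.cross(self.axis_x, self.axis_y), self.axis_z, atol=tol):
            raise DegenerateGeometryError("ICS frame not right-handed")

    def to_dict(self) -> dict:
        """Plain-record serialization for logging."""
        d = {
            "origin": self.origin.tolist(),
            "axis_x": self.axis_x.tolist(),
            "axis_y": self.axis_y.tolist(),
            "axis_z": self.axis_z.tolist(),
            "lamella_halfwidth_used": self.lamella_halfwidth_used,
        }
        for name in ("zmax_residue", "xref_residue"):
            rid = getattr(self, name)
            d[name] = None if rid is None else list(rid)
        return d


def compute_origin(cloud: CalphaCloud) -> np.ndarray:
    """Centroid of the cloud: component-wise mean of all C-alpha positions."""
    if len(cloud) == 0:
        raise EmptyStructureError("cannot compute origin of an empty cloud")
    return cloud.positions.mean(axis=0)


def _first_argmax(values: np.ndarray) -> int:
    """Index of the maximum, earliest occurrence on exact ties; logs near-ties."""
    idx = int(np.argmax(values))
    if len(values) > 1:
        runner = np.partition(values, -2)[-2]
        if values[idx] - runner < _NEAR_TIE:
            logger.warning(
                "near-tie in ICS extreme selection: top distances differ by %.3g Å",
                float(values[idx] - runner),
            )
    return idx


def compute_z_axis(
    cloud: CalphaCloud, origin: np.ndarray
) -> Tuple[np.ndarray, ResidueId]:
    """Unit vector from the origin toward the farthest C-alpha."""
    rel = cloud.positions - origin
    dists = np.linalg.norm(rel, axis=1)
    idx = _first_argmax(dists)
    if dists[idx] < 1e-9:
        raise DegenerateGeometryError("all points coincide with the origin")
    return rel[idx] / dists[idx], cloud.residues[idx]


def compute_x_axis(
    cloud: CalphaCloud,
    origin: np.ndarray,
    axis_z: np.ndarray,
    halfwidth: float = DEFAULT_LAMELLA_HALFWIDTH,
) -> Tuple[np.ndarray, ResidueId, float]:
    """x-axis from the extreme C-alpha of the lamellar slab around the xy-plane.

    Among C-alphas whose distance to the plane through ``origin`` normal to
    ``axis_z`` is at most ``halfwidth``, the one farthest from the origin is
    selected; x is the unit vector toward its in-plane projection P. An
    empty slab doubles the half-width until non-empty (with a warning).

    Returns (axis_x, selected residue, halfwidth actually used).
    """
    rel = cloud.positions - origin
    z_comp = rel @ axis_z
    dists = np.linalg.norm(rel, axis=1)
    hw = float(halfwidth)
    while True:
        in_slab = np.abs(z_comp) <= hw
        if np.any(in_slab):
            break
        hw *= 2.0
        warnings.warn(
            f"empty lamellar slab; widening half-width to {hw:g} Å", stacklevel=2
        )
    masked = np.where(in_slab, dists, -np.inf)
    idx = _first_argmax(masked)
    projection = rel[idx] - z_comp[idx] * axis_z
    norm = np.linalg.norm(projection)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "selected lamellar atom projects onto the origin; x-axis undefined"
        )
    return projection / norm, cloud.residues[idx], hw


def build_frame(
    cloud: CalphaCloud, lamella_halfwidth: float = DEFAULT_LAMELLA_HALFWIDTH
) -> ICSFrame:
    """Construct the full invariant frame of a cloud."""
    origin = compute_origin(cloud)
    axis_z, z_res = compute_z_axis(cloud, origin)
    axis_x, x_res, hw = compute_x_axis(cloud, origin, axis_z, lamella_halfwidth)
    axis_y = np.cross(axis_z, axis_x)
    axis_y /= np.linalg.norm(axis_y)
    frame = ICSFrame(
        origin=origin,
        axis_x=axis_x,
        axis_y=axis_y,
        axis_z=axis_z,
        zmax_residue=z_res,
        xref_residue=x_res,
        lamella_halfwidth_used=hw,
    )
    frame.validate()
    return frame


def transform_to_ics(cloud: CalphaCloud, frame: ICSFrame) -> CalphaCloud:
    """Express a cloud in the given frame: p -> ((p-O)·x, (p-O)·y, (p-O)·z)."""
    rel = cloud.positions - frame.origin
    return cloud.with_positions(rel @ frame.rotation.T)
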