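"""The Surface Roughness Index (SRI).

The SRI of a structure is an 8-valued vector. Component k is the
population standard deviation of the distances from the protein centre
(the ICS origin) of the *surface* C-alpha atoms that fall in octant k of
the invariant coordinate system. Octants holding fewer than two surface
points contribute an exact 0.0, which is why printed SRI tables can show
0.00 entries.

Two surface-detection rules are provided and recorded in the result:

``angular_shell`` (default)
    Directions around the centre are binned on an n_theta × n_phi
    longitude/latitude grid; in each non-empty bin the C-alpha of largest
    radial distance is a surface point. This is a star-shaped ("radially
    outermost") notion of surface, appropriate for globular clouds.

``convex_hull``
    Residues whose C-alpha is a vertex of the 3-D convex hull.

The same computation serves three roles: SRI_C (reference structure),
SRI_CM (candidate model) and SRI_P (predicted from images); the role tag
travels with the vector.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .errors import InsufficientPointsError, ParameterError
from .ics import build_frame, transform_to_ics
from .structure_io import CalphaCloud, ResidueId

__all__ = [
    "SRIVector",
    "detect_surface_residues",
    "octant_index",
    "compute_sri",
    "write_sri_csv",
    "read_sri_csv",
    "SRI_ROLES",
]

SRI_ROLES = ("calculated_reference", "calculated_model", "predicted")

DEFAULT_N_THETA = 18
DEFAULT_N_PHI = 9


@dataclass
class SRIVector:
    """8-valued surface roughness descriptor (Å), with per-octant counts."""

    values: np.ndarray
    role: str = "calculated_model"
    source_label: str = ""
    octant_counts: np.ndarray = field(default_factory=lambda: np.zeros(8, dtype=int))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(8)
        self.octant_counts = np.asarray(self.octant_counts, dtype=int).reshape(8)
        if self.role not in SRI_ROLES:
            raise ParameterError(f"unknown SRI role {self.role!r}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ParameterError("SRI values must be finite and non-negative")

    def __iter__(self):
        return iter(self.values)


def octant_index(point: Sequence[float]) -> int:
    """Octant (1..8) of a point in ICS coordinates.

    Convention: index = 1 + [x<0] + 2[y<0] + 4[z<0]; coordinates equal to
    zero count as non-negative, so octant 1 is the (+,+,+) region.
    """
    x, y, z = point
    return 1 + int(x < 0) + 2 * int(y < 0) + 4 * int(z < 0)


def _octant_indices(points: np.ndarray) -> np.ndarray:
    return (
        1
        + (points[:, 0] < 0).astype(int)
        + 2 * (points[:, 1] < 0).astype(int)
        + 4 * (points[:, 2] < 0).astype(int)
    )


def detect_surface_residues(
    cloud: CalphaCloud,
    method: str = "angular_shell",
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> set[ResidueId]:
    """Surface residues of a cloud already expressed in ICS coordinates.

    The cloud is assumed centred at the origin (the ICS origin is the
    protein centre). Points exactly at the origin have no direction and
    are never surface.
    """
    if len(cloud) < 4:
        raise InsufficientPointsError("surface detection needs at least 4 points")
    pts = cloud.positions
    if method == "convex_hull":
        hull = ConvexHull(pts)
        return {cloud.residues[i] for i in hull.vertices}
    if method != "angular_shell":
        raise ParameterError(f"unknown surface method {method!r}")
    if n_theta < 1 or n_phi < 1:
        raise ParameterError("angular grid must have at least one bin per axis")
    r = np.linalg.norm(pts, axis=1)
    nonzero = r > 1e-12
    theta = np.arctan2(pts[:, 1], pts[:, 0])  # [-pi, pi)
    with np.errstate(invalid="ignore"):
        cosphi = np.where(nonzero, pts[:, 2] / np.where(nonzero, r, 1.0), 0.0)
    phi = np.arccos(np.clip(cosphi, -1.0, 1.0))  # [0, pi]
    t_bin = np.clip(((theta + np.pi) / (2 * np.pi) * n_theta).astype(int), 0, n_theta - 1)
    p_bin = np.clip((phi / np.pi * n_phi).astype(int), 0, n_phi - 1)
    bin_id = t_bin * n_phi + p_bin
    surface: set[ResidueId] = set()
    for b in np.unique(bin_id[nonzero]):
        members = np.nonzero((bin_id == b) & nonzero)[0]
        best = members[np.argmax(r[members])]
        surface.add(cloud.residues[best])
    if not surface:
        raise InsufficientPointsError("no surface residues found")
    return surface


def compute_sri(
    cloud: CalphaCloud,
    role: str = "calculated_model",
    surface_method: str = "angular_shell",
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> SRIVector:
    """Compute the 8-valued SRI of a structure.

    Builds the invariant frame, transforms the cloud into it, detects
    surface residues, assigns each surface point to an octant, and takes
    the population standard deviation of the radial distances per octant.

    The two frame-defining residues (the farthest C-alpha and the
    lamellar x-reference) lie exactly on octant boundary planes by
    construction — their azimuth and octant membership are determined by
    floating-point noise, not geometry — so they are left out of surface
    detection and of the dispersion statistics.
    """
    frame = build_frame(cloud)
    ics_cloud = transform_to_ics(cloud, frame)
    frame_atoms = {frame.zmax_residue, frame.xref_residue}
    keep_det = [rid not in frame_atoms for rid in ics_cloud.residues]
    detection_cloud = CalphaCloud(
        residues=[r for r in ics_cloud.residues if r not in frame_atoms],
        positions=ics_cloud.positions[np.array(keep_det, dtype=bool)],
        source_label=ics_cloud.source_label,
    )
    surface = detect_surface_residues(
        detection_cloud, method=surface_method, n_theta=n_theta, n_phi=n_phi
    )
    keep = np.array([rid in surface for rid in ics_cloud.residues], dtype=bool)
    pts = ics_cloud.positions[keep]
    radii = np.linalg.norm(pts, axis=1)
    octants = _octant_indices(pts)
    values = np.zeros(8)
    counts = np.zeros(8, dtype=int)
    for k in range(1, 9):
        sel = octants == k
        counts[k - 1] = int(sel.sum())
        if counts[k - 1] > 1:
            values[k - 1] = float(np.std(radii[sel]))  # population SD
    return SRIVector(
        values=values,
        role=role,
        source_label=cloud.source_label,
        octant_counts=counts,
        metadata={
            "surface_method": surface_method,
            "n_theta": n_theta,
            "n_phi": n_phi,
            "n_surface": int(keep.sum()),
            "frame": frame.to_dict(),
        },
    )


_CSV_HEADER = ["source_label", "role"] + [f"sri_{k}" for k in range(1, 9)]


def write_sri_csv(vectors: Sequence[SRIVector], path_or_buf) -> None:
    """Write SRI vectors as CSV: source_label, role, sri_1..sri_8."""

    def _write(fh) -> None:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for v in vectors:
            w.writerow([v.source_label, v.role] + [f"{x:.6g}" for x in v.values])

    if hasattr(path_or_buf, "write"):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", newline="") as fh:
            _write(fh)


def read_sri_csv(path_or_buf) -> list[SRIVector]:
    """Read SRI vectors from the CSV layout written by :func:`write_sri_csv`."""

    def _read(fh) -> list[SRIVector]:
        rows = list(csv.reader(fh))
        if not rows:
            raise ParameterError("empty SRI CSV")
        header = rows[0]
        if header[:2] != ["source_label", "role"] or len(header) < 10:
            raise ParameterError("unexpected SRI CSV header")
        out = []
        for row in rows[1:]:
            if not row:
                continue
            out.append(
                SRIVector(
                    values=np.array([float(x) for x in row[2:10]]),
                    role=row[1],
                    source_label=row[0],
                )
            )
        return out

    if hasattr(path_or_buf, "read"):
        return _read(path_or_buf)
    with open(path_or_buf, newline="") as fh:
        return _read(fh)
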