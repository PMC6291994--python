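"""Ranking candidate structure models by SRI distance and by RMSD.

Given the SRI of every candidate model (SRI_CM) and a reference SRI —
either calculated from a deposited structure (SRI_C) or predicted from
micrographs (SRI_P) — each model is scored by the Euclidean distance
between its SRI and the reference (DC_MOD and DP_MOD respectively) and
the closest model is selected as best.

As an independent structural check, the C-alpha RMSD between a model and
the reference structure is computed after transforming *each* structure
into its own invariant coordinate system; no optimal superposition is
performed (a Kabsch mode exists for comparison but is never the
default). The report gathers distances, ranks, RMSDs and any externally
computed validation scores side by side.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError, ParameterError
from .ics import build_frame, transform_to_ics
from .sri import SRIVector
from .structure_io import CalphaCloud

__all__ = [
    "ValidationTable",
    "ModelRanking",
    "SelectionReport",
    "euclidean_distance",
    "rank_models",
    "rmsd_ics",
    "build_report",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class ValidationTable:
    """Externally computed per-model validation scores, passed through for
    side-by-side display (energy/KBSF, Ramachandran %, G-factor, Verify3D %).
    None of these are computed here."""

    scores: pd.DataFrame  # index: model label; columns: score names

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ParameterError("validation table has duplicate model labels")

    @classmethod
    def from_csv(cls, path) -> "ValidationTable":
        df = pd.read_csv(path)
        label_col = df.columns[0]
        return cls(scores=df.set_index(label_col))


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two 8-valued SRI vectors."""
    a = np.asarray(getattr(a, "values", a), dtype=float).reshape(-1)
    b = np.asarray(getattr(b, "values", b), dtype=float).reshape(-1)
    if a.shape != (8,) or b.shape != (8,):
        raise ParameterError("SRI distance expects two 8-vectors")
    return float(np.linalg.norm(a - b))


@dataclass
class ModelRanking:
    """Models ordered by ascending SRI distance to a reference."""

    labels: list[str]  # sorted, best first
    distances: dict[str, float]

    @property
    def best(self) -> str:
        return self.labels[0]

    def rank_of(self, label: str) -> int:
        return self.labels.index(label) + 1


def rank_models(
    model_sris: Sequence[SRIVector] | dict[str, Sequence[float]],
    reference: Sequence[float],
) -> ModelRanking:
    """Rank models by Euclidean SRI distance to the reference (best first).

    Ties are broken by model label order and logged, since the data
    cannot distinguish the tied models.
    """
    if isinstance(model_sris, dict):
        items = [(str(k), np.asarray(v, dtype=float)) for k, v in model_sris.items()]
    else:
        items = [
            (v.source_label or f"model_{i+1}", v.values)
            for i, v in enumerate(model_sris)
        ]
    if not items:
        raise ParameterError("rank_models needs at least one model")
    distances = {label: euclidean_distance(vec, reference) for label, vec in items}
    ordered = sorted(distances, key=lambda lab: (distances[lab], lab))
    dvals = sorted(distances.values())
    if len(dvals) > 1 and dvals[1] - dvals[0] < _TIE_TOL:
        logger.warning("SRI distance tie between leading models; broken by label order")
    return ModelRanking(labels=ordered, distances=distances)


def rmsd_ics(
    model: CalphaCloud,
    reference: CalphaCloud,
    pairing: str = "by_residue_number",
    mode: str = "ics",
) -> tuple[float, int]:
    """C-alpha RMSD between two structures compared in invariant frames.

    Both clouds are independently transformed to their own ICS; paired
    C-alpha distances d_i then give RMSD = sqrt(mean d_i^2). Pairing is
    by (chain, residue number, insertion code) intersection by default,
    or positional (``by_order``). ``mode="kabsch"`` instead optimally
    superposes the paired atoms (centred, SVD rotation) before the RMSD —
    an optional cross-check, not the default.

    Returns (rmsd, number of pairs).
    """
    if mode not in ("ics", "kabsch"):
        raise ParameterError(f"unknown RMSD mode {mode!r}")
    if mode == "ics":
        a = transform_to_ics(model, build_frame(model)).positions
        b = transform_to_ics(reference, build_frame(reference)).positions
    else:
        a = model.positions.astype(float)
        b = reference.positions.astype(float)

    if pairing == "by_order":
        n = min(len(a), len(b))
        pa, pb = a[:n], b[:n]
    elif pairing == "by_residue_number":
        index_b = {rid.key(): i for i, rid in enumerate(reference.residues)}
        ia, ib = [], []
        for i, rid in enumerate(model.residues):
            j = index_b.get(rid.key())
            if j is not None:
                ia.append(i)
                ib.append(j)
        pa, pb = a[ia], b[ib]
    else:
        raise ParameterError(f"unknown pairing {pairing!r}")
    if len(pa) == 0:
        raise PairingError("no shared C-alpha pairs between the two structures")

    if mode == "kabsch":
        ca, cb = pa - pa.mean(axis=0), pb - pb.mean(axis=0)
        U, _, Vt = np.linalg.svd(ca.T @ cb)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        pa, pb = ca @ R, cb
    diff = pa - pb
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))), len(pa)


@dataclass
class SelectionReport:
    """Per-model selection table plus the best-model verdicts."""

    table: pd.DataFrame  # index: model label; columns subset of
    # dc_mod, dp_mod, rank_dc, rank_dp, rmsd, rank_rmsd + validation scores
    best_by_dc: Optional[str] = None
    best_by_dp: Optional[str] = None
    best_by_rmsd: Optional[str] = None
    mean_rmsd: Optional[float] = None
    sd_rmsd: Optional[float] = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="model")

    def format_text(self) -> str:
        lines = [self.table.round(3).to_string()]
        if self.best_by_dc is not None:
            lines.append(f"best model by DC_MOD : {self.best_by_dc}")
        if self.best_by_dp is not None:
            lines.append(f"best model by DP_MOD : {self.best_by_dp}")
        if self.best_by_rmsd is not None:
            lines.append(f"best model by RMSD   : {self.best_by_rmsd}")
        if self.mean_rmsd is not None:
            lines.append(
                f"mean RMSD over models: {self.mean_rmsd:.2f} ± {self.sd_rmsd:.2f} Å"
            )
        return "\n".join(lines)


def build_report(
    model_sris: Sequence[SRIVector] | dict[str, Sequence[float]],
    sri_c: Optional[Sequence[float]] = None,
    sri_p: Optional[Sequence[float]] = None,
    structures: Optional[dict[str, CalphaCloud]] = None,
    reference_structure: Optional[CalphaCloud] = None,
    validation: Optional[ValidationTable] = None,
    pairing: str = "by_residue_number",
) -> SelectionReport:
    """Assemble the full model-selection report.

    ``sri_c`` / ``sri_p`` fill the DC_MOD / DP_MOD columns (at least one
    must be given); ``structures`` plus ``reference_structure`` fill the
    ICS-frame RMSD column with its mean ± population SD; a
    :class:`ValidationTable` is appended untouched.
    """
    if sri_c is None and sri_p is None:
        raise ParameterError("need at least one reference SRI (sri_c or sri_p)")
    if isinstance(model_sris, dict):
        labels = [str(k) for k in model_sris]
    else:
        labels = [
            v.source_label or f"model_{i+1}" for i, v in enumerate(model_sris)
        ]
    df = pd.DataFrame(index=pd.Index(labels, name="model"))
    report = SelectionReport(table=df)

    for ref, col, attr in ((sri_c, "dc_mod", "best_by_dc"), (sri_p, "dp_mod", "best_by_dp")):
        if ref is None:
            continue
        ranking = rank_models(model_sris, ref)
        df[col] = [ranking.distances[lab] for lab in labels]
        df[f"rank_{col[:2]}"] = [ranking.rank_of(lab) for lab in labels]
        setattr(report, attr, ranking.best)

    if structures is not None and reference_structure is not None:
        rmsds = {}
        for lab in labels:
            cloud = structures.get(lab)
            if cloud is not None:
                rmsds[lab], _ = rmsd_ics(cloud, reference_structure, pairing=pairing)
        if rmsds:
            df["rmsd"] = [rmsds.get(lab, np.nan) for lab in labels]
            order = sorted(rmsds, key=lambda lab: (rmsds[lab], lab))
            df["rank_rmsd"] = [
                order.index(lab) + 1 if lab in rmsds else np.nan for lab in labels
            ]
            report.best_by_rmsd = order[0]
            vals = np.array([rmsds[lab] for lab in rmsds])
            report.mean_rmsd = float(vals.mean())
            report.sd_rmsd = float(vals.std())  # population SD

    if validation is not None:
        for col in validation.scores.columns:
            df[col] = validation.scores[col].reindex(df.index)

    assert _best_consistent(report)
    return report


def _best_consistent(report: SelectionReport) -> bool:
    df = report.table
    for col, best in (
        ("dc_mod", report.best_by_dc),
        ("dp_mod", report.best_by_dp),
        ("rmsd", report.best_by_rmsd),
    ):
        if best is not None and col in df:
            series = df[col].dropna()
            if not np.isclose(series[best], series.min()):
                return False
    return True
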