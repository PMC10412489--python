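"""Per-branch pressure and flow-energy indices of the comparative method.

Three indices are computed at a measurement plane downstream of each
stenosis, from the paired stenotic/reference solutions run under identical
flows:

* ``FFR_sten = (P_d / P_a)_sten`` — the classical pressure ratio in the
  stenotic tree; mixes lesion losses with ordinary distal taper losses.
* ``FFR_rec  = (P_d / P_a)_rec`` — the same ratio in the virtually healed
  tree; the patient's healthy baseline at that location.
* ``EFR = (P_total_d)_sten / (P_total_d)_rec`` — the energy flow reference
  index.  Because both models carry the same flows, the ratio of distal
  energy flows ``EF = P_total·Q`` collapses to a total-pressure ratio, and
  the static variant collapses to FFR_sten/FFR_rec.  EFR equals 1 exactly
  in branches the lesion does not feed and decreases toward 0 with lesion
  severity, independent of how deep the branch sits in the tree.

Both FFR variants (with and without subtracting the zero-flow pressure P0)
are reported: a catheter measurement includes P0, so the unsubtracted ratio
is the clinical convention and the default.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from corovast.geometry import (Lesion, Segment, VesselTree, branch_chains,
                               diameter_at)
from corovast.hemodynamics import BoundaryConditions, SolutionField

__all__ = [
    "MeasurementPlane", "BranchIndices", "IndexReport",
    "energy_flow", "ffr_index", "efr", "efr_static",
    "select_measurement_planes", "build_report",
    "FFR_SIGNIFICANCE_CUTOFF", "EFR_SIGNIFICANCE_CUTOFF",
]

#: preliminary significance cut-offs (flags only, not a clinical claim)
FFR_SIGNIFICANCE_CUTOFF = 0.81
EFR_SIGNIFICANCE_CUTOFF = 0.85


@dataclass(frozen=True)
class MeasurementPlane:
    """A cross-section where indices are evaluated.

    ``rationale`` records why the plane sits where it does:
    ``distal_to_lesion`` (offset past the stenosis where flow has
    redeveloped), ``branch_terminus`` (no lesion on the branch, or no
    downstream span left), or ``user``.
    """

    segment_id: str
    s: float  # mm, segment-local arclength
    rationale: str = "user"
    warning: str | None = None


@dataclass
class BranchIndices:
    """All indices of one branch at its measurement plane (pressures in Pa)."""

    branch: str
    plane: MeasurementPlane
    P_d_sten: float
    P_d_rec: float
    P_total_d_sten: float
    P_total_d_rec: float
    P_a: float
    Q: float  # m³/s through the plane
    FFR_sten: float = field(init=False)
    FFR_rec: float = field(init=False)
    EFR_static: float = field(init=False)
    EFR_total: float = field(init=False)
    EF_d_sten: float = field(init=False)
    EF_d_rec: float = field(init=False)
    include_P0: bool = False
    P0: float = 0.0

    def __post_init__(self) -> None:
        self.FFR_sten = ffr_index(self.P_d_sten, self.P_a, self.P0,
                                  self.include_P0)
        self.FFR_rec = ffr_index(self.P_d_rec, self.P_a, self.P0,
                                 self.include_P0)
        self.EFR_static = efr_static(self.FFR_sten, self.FFR_rec)
        self.EFR_total = efr(self.P_total_d_sten, self.P_total_d_rec)
        self.EF_d_sten = energy_flow(self.P_total_d_sten, self.Q)
        self.EF_d_rec = energy_flow(self.P_total_d_rec, self.Q)
        for name in ("FFR_sten", "FFR_rec", "EFR_static", "EFR_total"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite index {name}")

    @property
    def flag_significant(self) -> bool:
        return (self.FFR_sten <= FFR_SIGNIFICANCE_CUTOFF
                or self.EFR_total <= EFR_SIGNIFICANCE_CUTOFF)


def energy_flow(P_total: float, Q: float) -> float:
    """Mechanical energy flow rate EF = P_total·Q in watts."""
    return P_total * Q


def ffr_index(P_d: float, P_a: float, P0: float = 0.0,
              include_P0: bool = False) -> float:
    """Fractional flow reserve from distal and aortic static pressures.

    Default (``include_P0=False``) is the clinical convention ``P_d/P_a``.
    With ``include_P0=True`` the zero-flow pressure is subtracted from both:
    ``(P_d − P0)/(P_a − P0)``.
    """
    denom = (P_a - P0) if include_P0 else P_a
    if denom <= 0:
        raise ValueError("FFR denominator must be positive")
    return ((P_d - P0) / denom) if include_P0 else (P_d / denom)


def efr(P_total_d_sten: float, P_total_d_rec: float) -> float:
    """Energy flow reference index (total-pressure variant).

    Ratio of distal total pressure, stenotic over reconstructed; the flow
    cancels because both models carry identical flows.
    """
    if P_total_d_rec <= 0:
        raise ValueError("reference distal total pressure must be positive")
    return P_total_d_sten / P_total_d_rec


def efr_static(FFR_sten: float, FFR_rec: float) -> float:
    """Static-pressure EFR variant: FFR_sten / FFR_rec."""
    if FFR_rec <= 0:
        raise ValueError("FFR_rec must be positive")
    return FFR_sten / FFR_rec


def select_measurement_planes(tree: VesselTree, lesions: Sequence[Lesion],
                              offset_diameters: float = 6.0
                              ) -> list[MeasurementPlane]:
    """Choose one measurement plane per named branch.

    A lesioned branch gets a plane ``offset_diameters`` local reference
    diameters past the end of its most severe lesion (clipped to 90% of the
    remaining branch length past the lesion) — far enough downstream that
    the flow has redeveloped.  A branch without lesions gets a terminus
    plane.  A lesion ending too close to the terminus degrades to a
    terminus plane with a warning flag.
    """
    chains = branch_chains(tree)
    seg_to_branch = {seg.id: name for name, chain in chains.items()
                     for seg in chain}
    worst: dict[str, Lesion] = {}
    for les in lesions:
        branch = seg_to_branch[les.segment_id]
        if (branch not in worst or les.percent_diameter_stenosis
                > worst[branch].percent_diameter_stenosis):
            worst[branch] = les

    planes: list[MeasurementPlane] = []
    for name, chain in chains.items():
        terminus = chain[-1]
        if name not in worst:
            planes.append(MeasurementPlane(terminus.id,
                                           float(terminus.s[-1]),
                                           "branch_terminus"))
            continue
        les = worst[name]
        seg = tree.segments[les.segment_id]
        # branch coordinate of the lesion end
        offset = 0.0
        for c in chain:
            if c.id == seg.id:
                break
            offset += c.length
        lesion_end_b = offset + (les.s_end - seg.s[0])
        total = sum(c.length for c in chain)
        d_ref = 2.0 * math.sqrt(les.reference_area_at_min / math.pi)
        remaining = total - lesion_end_b
        if remaining <= 0:
            planes.append(MeasurementPlane(
                terminus.id, float(terminus.s[-1]), "branch_terminus",
                warning=f"lesion on {name} reaches the branch terminus; "
                        "no undisturbed downstream span"))
            continue
        plane_b = lesion_end_b + min(offset_diameters * d_ref,
                                     0.9 * remaining)
        warn = None
        if offset_diameters * d_ref > 0.9 * remaining:
            warn = (f"branch {name}: downstream span too short for a "
                    f"{offset_diameters:g}-diameter offset; plane clipped")
        # branch coordinate -> segment-local
        acc = 0.0
        for c in chain:
            if plane_b <= acc + c.length or c is chain[-1]:
                s_local = c.s[0] + min(plane_b - acc, c.length)
                planes.append(MeasurementPlane(c.id, float(s_local),
                                               "distal_to_lesion",
                                               warning=warn))
                break
            acc += c.length
    planes.sort(key=lambda p: p.segment_id)
    return planes


@dataclass
class IndexReport:
    """Per-branch index table plus lesion table and run provenance."""

    branches: list[BranchIndices]
    lesions: list[Lesion]
    bc: BoundaryConditions
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            rows.append({
                "branch": b.branch,
                "plane_segment": b.plane.segment_id,
                "plane_s_mm": b.plane.s,
                "FFR_sten": b.FFR_sten,
                "FFR_rec": b.FFR_rec,
                "EFR_total": b.EFR_total,
                "EFR_static": b.EFR_static,
                "EF_sten_W": b.EF_d_sten,
                "EF_rec_W": b.EF_d_rec,
                "P_d_sten_kPa": b.P_d_sten / 1000.0,
                "P_d_rec_kPa": b.P_d_rec / 1000.0,
                "flag_significant": b.flag_significant,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "branches": [
                {**{k: v for k, v in asdict(b).items() if k != "plane"},
                 "plane": asdict(b.plane)}
                for b in self.branches
            ],
            "lesions": [asdict(l) for l in self.lesions],
            "boundary_conditions": {
                "P_a_Pa": self.bc.P_a,
                "P0_Pa": self.bc.P0,
                "Q_in_m3_s": self.bc.Q_in,
                "Q_req_m3_s": self.bc.Q_req,
                "R_Pa_s_m3": self.bc.R,
            },
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _interp_at(field_: SolutionField, plane: MeasurementPlane,
               seg: Segment) -> tuple[float, float, float]:
    """(P, P_total, Q) interpolated at a plane (SI)."""
    sol = field_.segments[plane.segment_id]
    s_local = (plane.s - seg.s[0]) * 1e-3  # solver s starts at 0, in m
    p = float(np.interp(s_local, sol.s, sol.P))
    pt = float(np.interp(s_local, sol.s, sol.P_total))
    return p, pt, sol.Q


def build_report(field_sten: SolutionField, field_rec: SolutionField,
                 planes: Sequence[MeasurementPlane],
                 lesions: Sequence[Lesion], bc: BoundaryConditions,
                 tree: VesselTree, include_P0: bool = False,
                 provenance: dict | None = None) -> IndexReport:
    """Assemble the per-branch index table from a paired solution.

    One row per measurement plane (one plane per named branch); the lesion
    table keeps every detected lesion, with the per-vessel maximal severity
    already reflected in the plane selection.
    """
    for name, f in (("stenotic", field_sten), ("reference", field_rec)):
        if not f.converged:
            raise ValueError(f"{name} solution is not converged "
                             f"(residual {f.residual:g}); refusing to report")
    rows = []
    for plane in planes:
        seg = tree.segments[plane.segment_id]
        p_s, pt_s, q = _interp_at(field_sten, plane, seg)
        p_r, pt_r, _ = _interp_at(field_rec, plane, seg)
        if plane.warning:
            warnings.warn(plane.warning, stacklevel=2)
        rows.append(BranchIndices(
            branch=seg.name, plane=plane,
            P_d_sten=p_s, P_d_rec=p_r,
            P_total_d_sten=pt_s, P_total_d_rec=pt_r,
            P_a=bc.P_a, Q=q, include_P0=include_P0, P0=bc.P0))
    rows.sort(key=lambda b: b.branch)
    return IndexReport(branches=rows, lesions=list(lesions), bc=bc,
                       provenance=provenance or {})
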