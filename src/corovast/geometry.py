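"""Vessel-tree data model, file I/O and the synthetic coronary-tree generator.

A vessel tree is a rooted tree of segments; each segment carries an ordered
1D lumen profile (arclength ``s`` in mm, cross-sectional area in mm²).  This
is the 1D abstraction of a segmented coronary lumen: 3D coordinates are not
kept, only the quantities the reduced-order flow model needs.

Units at this layer are the clinical I/O units (mm, mm²).  The flow solver
converts to SI internally.

A *branch* is a maximal chain of same-named segments (e.g. the LAD proximal
and distal segments on either side of the D1 take-off together form the LAD
branch); helpers for walking branches live here because both the lesion
generator and the reporting layer need them.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "FluidProperties", "LumenPoint", "Segment", "VesselTree", "Lesion",
    "SchemaError", "TreeValidationError",
    "load_tree", "save_tree", "diameter_at", "percent_stenosis",
    "make_synthetic_tree", "branch_chains", "branch_length",
    "TREE_FORMAT_NAME",
]

TREE_FORMAT_NAME = "corovast-tree-v1"

#: number of significant digits used when serializing profile numbers
_SERIAL_DIGITS = 9


class SchemaError(ValueError):
    """A tree file does not conform to the on-disk schema."""


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (cycle, orphan, bad profile)."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid.

    Defaults are the standard whole-blood values used in coronary CFD:
    density 1056 kg/m³ and dynamic viscosity 3.4 cP.
    """

    density: float = 1056.0          # kg/m³
    dynamic_viscosity: float = 3.4e-3  # Pa·s

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.dynamic_viscosity > 0):
            raise ValueError("density and viscosity must be strictly positive")


@dataclass(frozen=True)
class LumenPoint:
    """One sample of the lumen profile: arclength s (mm), area (mm²)."""

    s: float
    area: float

    def __post_init__(self) -> None:
        if not (self.s >= 0 and math.isfinite(self.s)):
            raise ValueError(f"arclength must be finite and >= 0, got {self.s}")
        if not (self.area > 0 and math.isfinite(self.area)):
            raise ValueError(f"area must be finite and > 0, got {self.area}")


class Segment:
    """A vessel segment: an ordered lumen profile between two junctions.

    Parameters
    ----------
    id : str
        Unique token within the tree.
    name : str
        Branch label (LM, LAD, D1, CX, OM1, ...).  Several segments may share
        a name; together they form one named branch.
    parent_id : str or None
        Parent segment id; None for the root.
    points : sequence of LumenPoint, or (n, 2) array-like
        Profile samples with strictly increasing arclength.
    is_outlet : bool
        Whether the distal end is a model outlet.
    """

    __slots__ = ("id", "name", "parent_id", "is_outlet", "s", "area")

    def __init__(self, id: str, name: str, parent_id: str | None,
                 points: Sequence[LumenPoint] | np.ndarray,
                 is_outlet: bool = False) -> None:
        self.id = str(id)
        self.name = str(name)
        self.parent_id = None if parent_id is None else str(parent_id)
        self.is_outlet = bool(is_outlet)
        if len(points) and isinstance(points[0], LumenPoint):
            arr = np.asarray([(p.s, p.area) for p in points], dtype=float)
        else:
            arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise TreeValidationError(
                f"segment {self.id!r}: profile needs >= 2 (s, area) samples")
        self.s = np.ascontiguousarray(arr[:, 0])
        self.area = np.ascontiguousarray(arr[:, 1])
        if not np.all(np.isfinite(arr)):
            raise TreeValidationError(
                f"segment {self.id!r}: non-finite profile value")
        if np.any(np.diff(self.s) <= 0):
            raise TreeValidationError(
                f"segment {self.id!r}: arclength must be strictly increasing")
        if self.s[0] < 0:
            raise TreeValidationError(
                f"segment {self.id!r}: arclength must be >= 0")
        if np.any(self.area <= 0):
            raise TreeValidationError(
                f"segment {self.id!r}: areas must be strictly positive")

    @property
    def points(self) -> list[LumenPoint]:
        return [LumenPoint(float(s), float(a))
                for s, a in zip(self.s, self.area)]

    @property
    def length(self) -> float:
        """Segment arclength span in mm."""
        return float(self.s[-1] - self.s[0])

    def copy(self) -> "Segment":
        return Segment(self.id, self.name, self.parent_id,
                       np.column_stack([self.s, self.area]), self.is_outlet)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Segment):
            return NotImplemented
        return (self.id == other.id and self.name == other.name
                and self.parent_id == other.parent_id
                and self.is_outlet == other.is_outlet
                and np.array_equal(self.s, other.s)
                and np.array_equal(self.area, other.area))

    def __repr__(self) -> str:
        return (f"Segment(id={self.id!r}, name={self.name!r}, "
                f"parent={self.parent_id!r}, n={len(self.s)}, "
                f"span=[{self.s[0]:g}, {self.s[-1]:g}] mm)")


class VesselTree:
    """A rooted tree of :class:`Segment` objects.

    Invariants (checked on construction): exactly one root, parent links form
    a connected acyclic tree, every leaf is flagged as an outlet.  No lumen
    continuity is imposed at junctions — the cross-section may step where a
    daughter branches off.
    """

    def __init__(self, segments: Iterable[Segment],
                 metadata: Mapping | None = None) -> None:
        segs = list(segments)
        if not segs:
            raise TreeValidationError("tree has no segments")
        self.segments: dict[str, Segment] = {}
        for seg in segs:
            if seg.id in self.segments:
                raise TreeValidationError(f"duplicate segment id {seg.id!r}")
            self.segments[seg.id] = seg
        self.metadata: dict = dict(metadata or {})
        roots = [s.id for s in segs if s.parent_id is None]
        if len(roots) != 1:
            raise TreeValidationError(
                f"tree must have exactly one root, found {len(roots)}")
        self.root_id: str = roots[0]
        self._children: dict[str, list[str]] = {sid: [] for sid in self.segments}
        for seg in segs:
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise TreeValidationError(
                        f"segment {seg.id!r}: unknown parent {seg.parent_id!r}")
                self._children[seg.parent_id].append(seg.id)
        # connectivity / acyclicity: every segment must reach the root
        for seg in segs:
            seen = set()
            cur = seg
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise TreeValidationError(
                        f"cycle in parent links through {cur.id!r}")
                seen.add(cur.id)
                cur = self.segments[cur.parent_id]
            if cur.id != self.root_id:
                raise TreeValidationError(
                    f"segment {seg.id!r} is disconnected from the root")
        for sid, kids in self._children.items():
            if not kids and not self.segments[sid].is_outlet:
                raise TreeValidationError(
                    f"leaf segment {sid!r} is not flagged as an outlet")

    # -- topology helpers -------------------------------------------------
    def children(self, segment_id: str) -> list[Segment]:
        return [self.segments[c] for c in self._children[segment_id]]

    @property
    def root(self) -> Segment:
        return self.segments[self.root_id]

    @property
    def outlet_ids(self) -> list[str]:
        return [sid for sid, seg in self.segments.items() if seg.is_outlet]

    def walk(self) -> Iterable[Segment]:
        """Depth-first, root first; children in insertion order."""
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            yield self.segments[sid]
            stack.extend(reversed(self._children[sid]))

    def path_to_root(self, segment_id: str) -> list[Segment]:
        """Segments from ``segment_id`` up to and including the root."""
        out = [self.segments[segment_id]]
        while out[-1].parent_id is not None:
            out.append(self.segments[out[-1].parent_id])
        return out

    def inlet_diameter(self) -> float:
        """Diameter (mm) of the first cross-section of the root segment."""
        return 2.0 * math.sqrt(self.root.area[0] / math.pi)

    def copy(self) -> "VesselTree":
        return VesselTree([s.copy() for s in self.segments.values()],
                          metadata=json.loads(json.dumps(self.metadata)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselTree):
            return NotImplemented
        return (set(self.segments) == set(other.segments)
                and all(self.segments[k] == other.segments[k]
                        for k in self.segments))

    def equals(self, other: "VesselTree", rtol: float = 1e-8) -> bool:
        """Equality up to the declared serialization precision."""
        if set(self.segments) != set(other.segments):
            return False
        for k, a in self.segments.items():
            b = other.segments[k]
            if (a.name != b.name or a.parent_id != b.parent_id
                    or a.is_outlet != b.is_outlet
                    or not np.allclose(a.s, b.s, rtol=rtol, atol=0)
                    or not np.allclose(a.area, b.area, rtol=rtol, atol=0)):
                return False
        return True

    def __repr__(self) -> str:
        return (f"VesselTree(root={self.root_id!r}, "
                f"{len(self.segments)} segments, "
                f"{len(self.outlet_ids)} outlets)")


@dataclass
class Lesion:
    """A stenosis interval detected (or planted) on one segment.

    ``percent_diameter_stenosis`` follows the clinical diameter-reduction
    convention: 100·(1 − sqrt(min_area / reference_area_at_min)).
    """

    segment_id: str
    s_start: float
    s_end: float
    min_area: float
    reference_area_at_min: float
    percent_diameter_stenosis: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.s_start < self.s_end:
            raise ValueError("lesion interval must satisfy s_start < s_end")
        if self.percent_diameter_stenosis is None:
            self.percent_diameter_stenosis = percent_stenosis(self)
        if not 0 <= self.percent_diameter_stenosis < 100:
            raise ValueError("percent stenosis must lie in [0, 100)")


# ---------------------------------------------------------------------------
# geometric derived quantities
# ---------------------------------------------------------------------------

def diameter_at(segment: Segment, s: float) -> float:
    """Equivalent circular diameter D = 2·sqrt(A(s)/π) in mm.

    The area is linearly interpolated between profile samples.  ``s`` must
    lie within the segment's arclength span.
    """
    if not (segment.s[0] <= s <= segment.s[-1]):
        raise ValueError(
            f"s={s} outside segment span [{segment.s[0]}, {segment.s[-1]}]")
    area = float(np.interp(s, segment.s, segment.area))
    return 2.0 * math.sqrt(area / math.pi)


def percent_stenosis(lesion: Lesion) -> float:
    """Percent diameter stenosis of a lesion, in [0, 100)."""
    if lesion.reference_area_at_min <= lesion.min_area:
        if lesion.reference_area_at_min < lesion.min_area:
            warnings.warn(
                f"lesion on {lesion.segment_id!r}: reference area below "
                "minimal area; reporting 0% stenosis", stacklevel=2)
        return 0.0
    return 100.0 * (1.0 - math.sqrt(lesion.min_area
                                    / lesion.reference_area_at_min))


# ---------------------------------------------------------------------------
# branch chains (named vessels spanning several segments)
# ---------------------------------------------------------------------------

def branch_chains(tree: VesselTree) -> dict[str, list[Segment]]:
    """Group segments into named branches.

    A branch is the chain of same-named segments starting where the name
    first appears walking from the root.  Returns name → segments ordered
    proximal to distal.
    """
    chains: dict[str, list[Segment]] = {}
    for seg in tree.walk():
        parent_name = (tree.segments[seg.parent_id].name
                       if seg.parent_id else None)
        if seg.name != parent_name:
            chains.setdefault(seg.name, [])
        chains[seg.name].append(seg)
    return chains


def branch_length(chain: Sequence[Segment]) -> float:
    """Total arclength (mm) of a branch chain."""
    return float(sum(seg.length for seg in chain))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> float:
    """Quantize to the serialization precision (9 significant digits)."""
    return float(f"{x:.{_SERIAL_DIGITS}g}")


def _tree_to_dict(tree: VesselTree) -> dict:
    return {
        "format": TREE_FORMAT_NAME,
        "units": {"length": "mm", "area": "mm2"},
        "root": tree.root_id,
        "segments": [
            {
                "id": seg.id,
                "name": seg.name,
                "parent": seg.parent_id,
                "is_outlet": seg.is_outlet,
                "points": [{"s": _fmt(s), "area": _fmt(a)}
                           for s, a in zip(seg.s, seg.area)],
            }
            for seg in tree.walk()
        ],
        "metadata": tree.metadata,
    }


def save_tree(tree: VesselTree, path: str | Path) -> None:
    """Write a tree as corovast-tree-v1 JSON (or per-segment CSVs).

    The numeric formatting is stable: saving, loading and saving again
    produces an identical file.  A ``.csv`` suffix selects the CSV manifest
    layout instead of JSON.
    """
    if not isinstance(tree, VesselTree):
        raise TypeError("save_tree expects a VesselTree")
    for seg in tree.segments.values():
        if not (np.all(np.isfinite(seg.area)) and np.all(np.isfinite(seg.s))):
            raise ValueError(f"segment {seg.id!r} has non-finite values; "
                             "refusing to write")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _save_tree_csv(tree, path)
        return
    path.write_text(json.dumps(_tree_to_dict(tree), indent=1) + "\n")


def _save_tree_csv(tree: VesselTree, manifest_path: Path) -> None:
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in tree.walk():
        fname = f"{manifest_path.stem}_{seg.id}.csv"
        with open(manifest_path.parent / fname, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s_mm", "area_mm2"])
            for s, a in zip(seg.s, seg.area):
                w.writerow([f"{s:.{_SERIAL_DIGITS}g}",
                            f"{a:.{_SERIAL_DIGITS}g}"])
        rows.append([seg.id, seg.name, seg.parent_id or "",
                     int(seg.is_outlet), fname])
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "parent", "is_outlet", "file"])
        w.writerows(rows)


def load_tree(path: str | Path, format: str | None = None) -> VesselTree:
    """Load a vessel tree from corovast-tree-v1 JSON or a CSV manifest.

    The format is inferred from the suffix unless given explicitly.
    Schema problems raise :class:`SchemaError` naming the offending field;
    structural problems raise :class:`TreeValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "csv":
        return _load_tree_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be an object")
    if doc.get("format") != TREE_FORMAT_NAME:
        raise SchemaError(
            f"{path}: field 'format' must be {TREE_FORMAT_NAME!r}, "
            f"got {doc.get('format')!r}")
    segs_raw = doc.get("segments")
    if not isinstance(segs_raw, list) or not segs_raw:
        raise SchemaError(f"{path}: field 'segments' must be a non-empty list")
    segments = []
    for i, d in enumerate(segs_raw):
        for req in ("id", "name", "points"):
            if req not in d:
                raise SchemaError(
                    f"{path}: segments[{i}] missing field {req!r}")
        pts = d["points"]
        if not isinstance(pts, list):
            raise SchemaError(f"{path}: segments[{i}].points must be a list")
        try:
            arr = [(float(p["s"]), float(p["area"])) for p in pts]
        except (KeyError, TypeError, ValueError) as e:
            raise SchemaError(
                f"{path}: segments[{i}].points: bad 's'/'area' entry: {e}"
            ) from e
        segments.append(Segment(d["id"], d["name"], d.get("parent"),
                                np.asarray(arr), bool(d.get("is_outlet"))))
    tree = VesselTree(segments, metadata=doc.get("metadata") or {})
    declared_root = doc.get("root")
    if declared_root is not None and declared_root != tree.root_id:
        raise SchemaError(
            f"{path}: field 'root' is {declared_root!r} but the parent links "
            f"root at {tree.root_id!r}")
    return tree


def _load_tree_csv(manifest_path: Path) -> VesselTree:
    segments = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            for req in ("id", "name", "file"):
                if row.get(req) in (None, ""):
                    raise SchemaError(
                        f"{manifest_path}: manifest row missing {req!r}")
            prof_path = manifest_path.parent / row["file"]
            with open(prof_path, newline="") as pfh:
                pts = [(float(r["s_mm"]), float(r["area_mm2"]))
                       for r in csv.DictReader(pfh)]
            segments.append(Segment(row["id"], row["name"],
                                    row.get("parent") or None,
                                    np.asarray(pts),
                                    bool(int(row.get("is_outlet") or 0))))
    return VesselTree(segments)


# ---------------------------------------------------------------------------
# synthetic coronary tree generator
# ---------------------------------------------------------------------------

#: sampling pitch of generated profiles (mm)
SAMPLING_PITCH_MM = 0.25

# Branch plans: (id, name, parent_id, length mm, prox diam mm, dist diam mm,
# is_outlet).  Diameters are adult means: LM 4.32 mm with daughters tapering
# distally to the ~1.5 mm limit of CT segmentation.  The LAD and CX are each
# split into proximal/distal segments at the D1 / OM1 take-off so that all
# junctions fall at segment ends.
_TEMPLATES: dict[str, list[tuple]] = {
    "left": [
        ("LM",    "LM",  None,    10.0, 4.32, 4.15, False),
        ("LAD_p", "LAD", "LM",    40.0, 3.70, 2.90, False),
        ("LAD_d", "LAD", "LAD_p", 60.0, 2.70, 1.60, True),
        ("D1",    "D1",  "LAD_p", 45.0, 2.40, 1.30, True),
        ("CX_p",  "CX",  "LM",    30.0, 3.40, 2.80, False),
        ("CX_d",  "CX",  "CX_p",  50.0, 2.60, 1.50, True),
        ("OM1",   "OM1", "CX_p",  45.0, 2.40, 1.30, True),
    ],
    "right": [
        ("RCA_p", "RCA", None,    60.0, 3.90, 3.00, False),
        ("PDA",   "PDA", "RCA_p", 45.0, 2.30, 1.30, True),
        ("PLV",   "PLV", "RCA_p", 40.0, 2.20, 1.30, True),
    ],
    "single": [
        ("V1", "V1", None, 50.0, 3.00, 2.20, True),
    ],
}

_POSITION_ALIASES = {"prox": 0.15, "mid": 0.50, "dist": 0.80}


def _healthy_segments(template: str, noise_sd: float,
                      rng: np.random.Generator) -> list[Segment]:
    if template not in _TEMPLATES:
        raise ValueError(f"unknown template {template!r}; "
                         f"choose from {sorted(_TEMPLATES)}")
    segments = []
    for sid, name, parent, length, d0, d1, is_outlet in _TEMPLATES[template]:
        n = int(round(length / SAMPLING_PITCH_MM)) + 1
        s = np.linspace(0.0, length, n)
        diam = d0 + (d1 - d0) * s / length
        area = math.pi * (diam / 2.0) ** 2
        if noise_sd > 0:
            # spatially correlated wall irregularity (~2 mm), not white noise
            raw = gaussian_filter1d(rng.standard_normal(n), sigma=8.0,
                                    mode="nearest")
            sd = raw.std()
            if sd > 0:
                area = area + noise_sd * raw / sd
            area = np.maximum(area, 0.05 * area.max())
        segments.append(Segment(sid, name, parent,
                                np.column_stack([s, area]), is_outlet))
    return segments


def _cosine_bump(x: np.ndarray, center: float, length: float) -> np.ndarray:
    """Smooth bump: 1 at center, 0 outside [center - L/2, center + L/2]."""
    out = np.zeros_like(x)
    inside = np.abs(x - center) < length / 2.0
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * math.pi
                                      * (x[inside] - center) / length))
    return out


def make_synthetic_tree(
    template: str = "left",
    lesion_specs: Sequence[tuple] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VesselTree, list[Lesion]]:
    """Generate a synthetic coronary tree with parameterized stenoses.

    Stands in for CCTA segmentation: branch diameters follow adult mean
    values (LM 4.32 mm) with linear distal taper, sampled every 0.25 mm.
    Each lesion is a cosine-bump area reduction reaching the requested
    minimum diameter ``(1 - %DS/100) ×`` the local healthy diameter over the
    requested length.

    Parameters
    ----------
    template : {"left", "right", "single"}
        Branch layout.  "left" is LM → LAD + CX, LAD → D1, CX → OM1.
    lesion_specs : sequence of (branch, position, percent_DS, length_mm)
        ``position`` is the lesion center in mm along the named branch, or
        one of "prox"/"mid"/"dist" (15/50/80% of branch length).
    noise_sd : float
        Standard deviation (mm²) of spatially correlated area irregularity
        added to the healthy baseline.  0 gives exact analytic profiles.
    seed : int
        Seed for the irregularity; recorded in the tree metadata.
        Identical inputs give bitwise-identical trees.

    Returns
    -------
    (tree, truth_lesions)
        The stenotic tree and the planted lesions as ground truth (with the
        exact local reference areas), for detector/reconstruction testing.
        With no lesion specs the returned tree is the healthy template.
    """
    rng = np.random.default_rng(seed)
    segments = _healthy_segments(template, noise_sd, rng)
    by_id = {s.id: s for s in segments}
    chains: dict[str, list[Segment]] = {}
    for seg in segments:
        chains.setdefault(seg.name, []).append(seg)

    # validate specs and map branch coordinates to (segment, local interval)
    placed: list[tuple[Segment, float, float, float]] = []
    by_branch: dict[str, list[tuple[float, float]]] = {}
    for spec in lesion_specs:
        branch, position, pct, length = spec
        if not 0 <= pct <= 95:
            raise ValueError(f"percent stenosis {pct} outside [0, 95]")
        if branch not in chains:
            raise ValueError(f"unknown branch {branch!r} in template "
                             f"{template!r}")
        chain = chains[branch]
        total = branch_length(chain)
        if isinstance(position, str):
            try:
                center = _POSITION_ALIASES[position] * total
            except KeyError:
                raise ValueError(
                    f"position must be mm or one of {sorted(_POSITION_ALIASES)}"
                ) from None
        else:
            center = float(position)
        if not 0 <= center <= total:
            raise ValueError(f"lesion center {center} mm outside branch "
                             f"{branch!r} span (0–{total:g} mm)")
        for a, b in by_branch.get(branch, []):
            if center - length / 2 < b and center + length / 2 > a:
                raise ValueError(f"overlapping lesion specs on branch "
                                 f"{branch!r}")
        by_branch.setdefault(branch, []).append(
            (center - length / 2, center + length / 2))
        # branch coordinate -> segment-local coordinate
        offset = 0.0
        for seg in chain:
            if center <= offset + seg.length or seg is chain[-1]:
                local = seg.s[0] + (center - offset)
                placed.append((seg, local, float(pct), float(length)))
                break
            offset += seg.length

    truth: list[Lesion] = []
    for seg, center, pct, length in placed:
        healthy_area = seg.area.copy()
        ds = pct / 100.0
        bump = _cosine_bump(seg.s, center, length)
        factor = 1.0 - (1.0 - (1.0 - ds) ** 2) * bump
        seg.area[:] = healthy_area * factor
        i_min = int(np.argmin(seg.area / healthy_area))
        truth.append(Lesion(
            segment_id=seg.id,
            s_start=max(seg.s[0], center - length / 2),
            s_end=min(seg.s[-1], center + length / 2),
            min_area=float(seg.area[i_min]),
            reference_area_at_min=float(healthy_area[i_min]),
        ))

    meta = {
        "generator": "corovast synthetic",
        "template": template,
        "seed": int(seed),
        "noise_sd_mm2": float(noise_sd),
        "lesion_specs": [list(map(str, spec)) for spec in lesion_specs],
    }
    return VesselTree(list(by_id.values()), metadata=meta), truth
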