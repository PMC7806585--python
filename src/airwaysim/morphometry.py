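"""Characteristic airway geometry: upper airway, C-shaped trachea, bifurcating tree.

The conducting airways are represented as a strict binary tree of cylindrical
branch segments (trachea = generation 0) preceded by three elliptical
upper-airway sections (oral cavity, pharynx, larynx).  Bifurcation design
follows the classical power-law diameter relation

    d_P^x = d_A^x + d_B^x

between a parent branch P and its daughters A, B (x = 3 recovers Murray's
law), with a carinal ridge of radius r_c = (R_A + R_B) * c_c and a transition
zone beginning at a fixed fraction of the parent's axial length.  The trachea
is a circular tube cut by a posterior chord (pars membranacea), optionally
decorated with cartilaginous rings.

All geometric quantities are in centimetres unless stated otherwise
(ring dimensions are in millimetres, matching anatomical convention).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")
REGIONS = ("oral", "pharynx", "larynx", "trachea", "bif1", "bif2", "bif3", "peripheral")

#: region assigned to a branch of a given generation (trachea handled separately)
GENERATION_REGION = {0: "trachea", 1: "bif1", 2: "bif2", 3: "bif3"}


class StructuralError(ValueError):
    """Morphometry table or tree violates the binary-tree contract."""


class GeometryDomainError(ValueError):
    """A geometric argument is outside its physical domain."""


def _region_for_generation(g: int) -> str:
    return GENERATION_REGION.get(g, "peripheral")


@dataclass
class BifurcationSpec:
    """Design rules applied at every bifurcation.

    x_n : diameter-law exponent (3 = Murray's law).
    c_c : carinal curvature ratio, r_c = (R_A + R_B) * c_c.
    transition_fraction : fraction of the parent axial length at which the
        transition zone towards the daughters begins.
    """

    x_n: float = 3.0
    c_c: float = 0.1
    transition_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.x_n > 0:
            raise GeometryDomainError(f"x_n must be positive, got {self.x_n}")
        if not 0 < self.c_c < 1:
            raise GeometryDomainError(f"c_c must be in (0, 1), got {self.c_c}")
        if not 0 < self.transition_fraction < 1:
            raise GeometryDomainError(
                f"transition_fraction must be in (0, 1), got {self.transition_fraction}"
            )


@dataclass
class BranchSegment:
    id: str
    parent_id: str | None
    generation: int
    length: float  # cm
    diameter: float  # cm
    start_point: np.ndarray  # cm
    end_point: np.ndarray  # cm
    lobe: str = "none"
    region: str = "peripheral"
    child_ids: list[str] = field(default_factory=list)
    branching_angle: float = 0.0  # degrees from parent axis
    gravity_angle: float = 0.0  # degrees between branch axis and gravity

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise GeometryDomainError(f"branch {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise GeometryDomainError(f"branch {self.id}: diameter must be > 0")
        if self.lobe not in LOBES and self.lobe != "none":
            raise GeometryDomainError(f"branch {self.id}: unknown lobe {self.lobe!r}")
        if self.region not in REGIONS:
            raise GeometryDomainError(f"branch {self.id}: unknown region {self.region!r}")
        self.start_point = np.asarray(self.start_point, dtype=float)
        self.end_point = np.asarray(self.end_point, dtype=float)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def direction(self) -> np.ndarray:
        v = self.end_point - self.start_point
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    @property
    def csa(self) -> float:
        """Circular cross-sectional area, cm^2."""
        return math.pi * self.radius**2

    @property
    def is_terminal(self) -> bool:
        return len(self.child_ids) == 0


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation to the perimeter of an ellipse."""
    if a < 0 or b < 0:
        raise GeometryDomainError("semi-axes must be non-negative")
    if a + b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


@dataclass
class UpperAirwaySection:
    """Elliptical upper-airway tube (oral cavity, pharynx or larynx)."""

    name: str
    semi_axis_a: float  # cm
    semi_axis_b: float  # cm
    length: float  # cm

    def __post_init__(self) -> None:
        if self.name not in ("oral_cavity", "pharynx", "larynx"):
            raise GeometryDomainError(f"unknown upper-airway section {self.name!r}")
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0 or self.length <= 0:
            raise GeometryDomainError(f"section {self.name}: dimensions must be > 0")

    @property
    def csa(self) -> float:
        """Cross-sectional area, cm^2."""
        return math.pi * self.semi_axis_a * self.semi_axis_b

    @property
    def hydraulic_diameter(self) -> float:
        """4 * area / perimeter with Ramanujan's perimeter, cm."""
        return 4.0 * self.csa / ellipse_perimeter(self.semi_axis_a, self.semi_axis_b)

    @property
    def region(self) -> str:
        return {"oral_cavity": "oral", "pharynx": "pharynx", "larynx": "larynx"}[self.name]

    def scaled(self, s: float) -> "UpperAirwaySection":
        return UpperAirwaySection(self.name, self.semi_axis_a * s, self.semi_axis_b * s, self.length * s)


def c_shape_area(spec: "TracheaSpec") -> float:
    """Area of the tracheal C-shaped cross-section, cm^2.

    Full circle of radius d/2 minus the circular segment beyond the posterior
    chord at ``posterior_cut_offset`` from the centre.  An offset at or beyond
    the radius degenerates to the full circle (flagged with a warning).
    """
    r = spec.diameter / 2.0
    h = spec.posterior_cut_offset
    if h < 0:
        raise GeometryDomainError("posterior_cut_offset must be non-negative")
    full = math.pi * r * r
    if h >= r:
        warnings.warn("posterior cut offset >= radius: no cut, full circle", stacklevel=2)
        return full
    segment = r * r * math.acos(h / r) - h * math.sqrt(r * r - h * h)
    return full - segment


@dataclass
class TracheaSpec:
    diameter: float = 1.56  # cm
    posterior_cut_offset: float = 0.65  # cm from centre
    length: float = 10.0  # cm

    def __post_init__(self) -> None:
        if not self.diameter > 0 or not self.length > 0:
            raise GeometryDomainError("trachea diameter and length must be > 0")
        if not 0 < self.posterior_cut_offset:
            raise GeometryDomainError("posterior_cut_offset must be > 0")

    @property
    def csa_effective(self) -> float:
        """C-shape cross-sectional area, cm^2."""
        return c_shape_area(self)


@dataclass
class RingSpec:
    """Cartilaginous ring parametrization: step p, width L, depth d, fillet r (mm).

    Defaults are anatomically plausible (about two rings per centimetre,
    sub-millimetric relief); they are geometric annotations only unless the
    effective-roughness mode is enabled in the flow configuration.
    """

    step_p: float = 5.0  # mm
    width_L: float = 3.5  # mm
    depth_d: float = 0.5  # mm
    fillet_r: float = 0.3  # mm
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.width_L < self.step_p:
            raise GeometryDomainError("ring width_L must be smaller than step_p")
        if self.depth_d < 0:
            raise GeometryDomainError("ring depth_d must be non-negative")


@dataclass
class AirwayTree:
    branches: dict[str, BranchSegment]
    root_id: str
    upper_airway: list[UpperAirwaySection] = field(default_factory=list)
    trachea: TracheaSpec = field(default_factory=TracheaSpec)
    rings: RingSpec = field(default_factory=RingSpec)
    bif_spec: BifurcationSpec = field(default_factory=BifurcationSpec)
    #: per-parent diameter-law residual |d_P^x - d_A^x - d_B^x| / d_P^x
    diameter_law_residuals: dict[str, float] = field(default_factory=dict)
    #: branch id -> axial ring positions (cm from branch start), see add_rings
    ring_positions: dict[str, list[float]] = field(default_factory=dict)

    @property
    def max_generation(self) -> int:
        return max(b.generation for b in self.branches.values())

    @property
    def terminal_ids(self) -> list[str]:
        return [b.id for b in self.branches.values() if b.is_terminal]

    @property
    def lobes_present(self) -> set[str]:
        return {b.lobe for b in self.branches.values() if b.is_terminal}

    def children(self, branch_id: str) -> list[BranchSegment]:
        return [self.branches[c] for c in self.branches[branch_id].child_ids]

    def validate(self) -> None:
        roots = [b for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        if roots[0].id != self.root_id:
            raise StructuralError("root_id does not match the parentless branch")
        for b in self.branches.values():
            if len(b.child_ids) not in (0, 2):
                raise StructuralError(f"branch {b.id} has {len(b.child_ids)} children (expected 0 or 2)")
            if b.is_terminal and b.lobe == "none":
                raise StructuralError(f"terminal branch {b.id} carries no lobe label")
            for c in b.child_ids:
                if self.branches[c].generation != b.generation + 1:
                    raise StructuralError(f"generation of {c} is not parent generation + 1")
        # acyclicity / reachability
        seen: set[str] = set()
        stack = [self.root_id]
        while stack:
            bid = stack.pop()
            if bid in seen:
                raise StructuralError(f"cycle detected at branch {bid}")
            seen.add(bid)
            stack.extend(self.branches[bid].child_ids)
        if seen != set(self.branches):
            raise StructuralError(f"unreachable branches: {sorted(set(self.branches) - seen)}")
        if self.max_generation >= 4 and not set(LOBES) <= self.lobes_present:
            raise StructuralError("not all five lobe labels present on terminal branches")


def carinal_radius(R_A: float, R_B: float, c_c: float) -> float:
    """Carinal radius of curvature r_c = (R_A + R_B) * c_c, cm."""
    if R_A < 0 or R_B < 0:
        raise GeometryDomainError("daughter radii must be non-negative")
    return (R_A + R_B) * c_c


def transition_zone(parent: BranchSegment, bif_spec: BifurcationSpec) -> float:
    """Axial position (cm from branch start) where the bifurcation transition zone begins."""
    return bif_spec.transition_fraction * parent.length


MORPHOMETRY_COLUMNS = ["id", "parent_id", "generation", "length_cm", "diameter_cm", "dx", "dy", "dz", "lobe", "region"]


def build_tree(
    morphometry_table: pd.DataFrame,
    bif_spec: BifurcationSpec | None = None,
    trachea: TracheaSpec | None = None,
    upper_airway: list[UpperAirwaySection] | None = None,
    rings: RingSpec | None = None,
) -> AirwayTree:
    """Assemble an :class:`AirwayTree` from a morphometry table.

    The table follows the CSV dialect with columns
    ``id,parent_id,generation,length_cm,diameter_cm,dx,dy,dz,lobe,region``;
    direction vectors are normalized internally and child links inferred from
    ``parent_id``.  The diameter-law residual
    ``|d_P^x - d_A^x - d_B^x| / d_P^x`` is computed per bifurcation as a
    diagnostic and stored on the tree (it is never enforced on measured
    tables).
    """
    bif_spec = bif_spec or BifurcationSpec()
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in morphometry_table.columns]
    if missing:
        raise StructuralError(f"morphometry table missing columns: {missing}")
    table = morphometry_table.copy()
    table["id"] = table["id"].astype(str)
    ids = set(table["id"])
    if len(ids) != len(table):
        raise StructuralError("duplicate branch ids in morphometry table")

    gens = sorted(table["generation"].unique())
    if gens != list(range(len(gens))) or gens[0] != 0:
        raise StructuralError(f"generations must be contiguous from 0, got {gens}")

    branches: dict[str, BranchSegment] = {}
    # first pass: create segments (positions resolved in tree order below)
    rows = {str(r.id): r for r in table.itertuples(index=False)}
    parent_of = {}
    for bid, r in rows.items():
        pid = None if pd.isna(r.parent_id) or str(r.parent_id) in ("", "none", "None") else str(r.parent_id)
        if pid is not None and pid not in ids:
            raise StructuralError(f"branch {bid} references unknown parent {pid!r} (orphan)")
        parent_of[bid] = pid

    roots = [bid for bid, pid in parent_of.items() if pid is None]
    if len(roots) != 1:
        raise StructuralError(f"expected exactly one root row, found {len(roots)}")
    root_id = roots[0]

    children_of: dict[str, list[str]] = {bid: [] for bid in ids}
    for bid, pid in parent_of.items():
        if pid is not None:
            children_of[pid].append(bid)
    for bid, kids in children_of.items():
        if len(kids) not in (0, 2):
            raise StructuralError(f"branch {bid} has {len(kids)} children (expected 0 or 2)")

    # resolve positions root-first
    order = [root_id]
    i = 0
    while i < len(order):
        order.extend(sorted(children_of[order[i]]))
        i += 1
    for bid in order:
        r = rows[bid]
        d = np.array([r.dx, r.dy, r.dz], dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise StructuralError(f"branch {bid} has a zero direction vector")
        d /= n
        pid = parent_of[bid]
        start = np.zeros(3) if pid is None else branches[pid].end_point
        end = start + d * float(r.length_cm)
        if pid is None:
            ang = 0.0
        else:
            cosang = float(np.clip(np.dot(d, branches[pid].direction), -1.0, 1.0))
            ang = math.degrees(math.acos(cosang))
        gravity = np.array([0.0, 0.0, -1.0])
        grav_ang = math.degrees(math.acos(float(np.clip(np.dot(d, gravity), -1.0, 1.0))))
        lobe = str(r.lobe) if str(r.lobe) in LOBES else "none"
        region = str(r.region) if str(r.region) in REGIONS else _region_for_generation(int(r.generation))
        branches[bid] = BranchSegment(
            id=bid,
            parent_id=pid,
            generation=int(r.generation),
            length=float(r.length_cm),
            diameter=float(r.diameter_cm),
            start_point=start,
            end_point=end,
            lobe=lobe,
            region=region,
            child_ids=sorted(children_of[bid]),
            branching_angle=ang,
            gravity_angle=grav_ang,
        )

    tree = AirwayTree(
        branches=branches,
        root_id=root_id,
        upper_airway=upper_airway or [],
        trachea=trachea or TracheaSpec(diameter=float(branches[root_id].diameter), length=float(branches[root_id].length)),
        rings=rings or RingSpec(),
        bif_spec=bif_spec,
    )
    tree.validate()

    x = bif_spec.x_n
    for b in branches.values():
        if len(b.child_ids) == 2:
            da, db = (branches[c].diameter for c in b.child_ids)
            tree.diameter_law_residuals[b.id] = abs(b.diameter**x - da**x - db**x) / b.diameter**x
    return tree


UPPER_AIRWAY_ORDER = ("oral_cavity", "pharynx", "larynx")


def build_upper_airway(
    section_table: pd.DataFrame,
    trachea: TracheaSpec,
    scale_mode: str = "fit_trachea",
) -> list[UpperAirwaySection]:
    """Build the elliptical upper-airway sections, rescaled to fit the trachea.

    The section table carries rows ``oral_cavity, pharynx, larynx`` in
    mouth-to-glottis order plus a ``trachea_end`` row whose equivalent
    diameter is the unscaled tracheal end of the source model.  In
    ``fit_trachea`` mode every linear dimension is multiplied by the single
    factor ``trachea.diameter / unscaled tracheal-end diameter``; ``identity``
    returns the fixture dimensions unchanged.
    """
    names = list(section_table["name"])
    core = [n for n in names if n != "trachea_end"]
    if core != list(UPPER_AIRWAY_ORDER):
        raise GeometryDomainError(
            f"upper-airway sections must appear in order {UPPER_AIRWAY_ORDER}, got {core}"
        )
    sections = []
    trachea_end_d = None
    for r in section_table.itertuples(index=False):
        if r.name == "trachea_end":
            trachea_end_d = 2.0 * math.sqrt(float(r.semi_axis_a_cm) * float(r.semi_axis_b_cm))
            continue
        sections.append(
            UpperAirwaySection(r.name, float(r.semi_axis_a_cm), float(r.semi_axis_b_cm), float(r.length_cm))
        )
    if scale_mode == "identity":
        scaled = sections
    elif scale_mode == "fit_trachea":
        if trachea_end_d is None:
            raise GeometryDomainError("fit_trachea scaling requires a trachea_end row")
        s = trachea.diameter / trachea_end_d
        scaled = [sec.scaled(s) for sec in sections]
    else:
        raise GeometryDomainError(f"unknown scale_mode {scale_mode!r}")
    larynx = next(sec for sec in scaled if sec.name == "larynx")
    if any(sec.csa < larynx.csa for sec in scaled):
        raise GeometryDomainError("larynx is not the minimum-CSA upper-airway section")
    return scaled


def add_rings(tree: AirwayTree, rings: RingSpec | None = None) -> AirwayTree:
    """Annotate cartilaginous ring positions on the trachea and main bronchi.

    Rings are placed perpendicular to the branch axis every ``step_p`` mm
    (count = floor(branch length / step)); generations >= 2 are never ringed.
    The annotation is purely geometric: flow and deposition are unaffected
    unless the effective-roughness flow option is turned on.
    """
    rings = rings or tree.rings
    if not rings.enabled:
        return tree
    tree.rings = rings
    step_cm = rings.step_p / 10.0
    tree.ring_positions = {}
    for b in tree.branches.values():
        if b.generation <= 1:  # trachea and main bronchi only
            n = int(b.length / step_cm)
            tree.ring_positions[b.id] = [(i + 0.5) * step_cm for i in range(n)]
    return tree


def ring_count(tree: AirwayTree, branch_id: str) -> int:
    return len(tree.ring_positions.get(branch_id, []))


def export_surface(tree: AirwayTree, path: str, fmt: str | None = None):
    """Write a triangulated surface of the airway model (STL by default).

    Thin wrapper around :mod:`airwaysim.surface`.
    """
    from . import surface

    return surface.export_surface(tree, path, fmt=fmt)


def tree_metadata(tree: AirwayTree) -> dict:
    """Round-trippable summary written alongside exported surfaces."""
    return {
        "branch_count": len(tree.branches),
        "terminal_count": len(tree.terminal_ids),
        "max_generation": tree.max_generation,
        "total_centerline_length_cm": float(sum(b.length for b in tree.branches.values())),
    }


def write_tree_metadata(tree: AirwayTree, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(tree_metadata(tree), fh, indent=2, sort_keys=True)
        fh.write("\n")
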