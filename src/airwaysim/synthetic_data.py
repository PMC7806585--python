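"""Generators for every input the pipeline needs, so nothing is downloaded.

Two morphometry-table modes are provided:

* ``weibel_symmetric`` — the classical fully symmetric bifurcating tree
  (every daughter pair identical, diameters following the power-law diameter
  relation exactly).  Deterministic; the strongest end-to-end oracle, since
  flow and deposition must be exactly left/right mirror symmetric on it.
* ``characteristic_asymmetric`` — a five-lobed asymmetric tree to generation
  6 (64 peripheral outlets) emulating an average adult male tracheobronchial
  tree: anatomical trachea and main-bronchi dimensions, Murray-exact
  bifurcations, mild seeded within-lobe asymmetry, and lobar-root diameters
  calibrated once (deterministic fixed-point iteration) so that an
  equal-outlet-pressure laminar solve reproduces the physiological lobar
  ventilation partition (RUL 19, RML 9, RLL 29, LUL 26, LLL 17 % -> right
  lung 57 %).

The characteristic table and the synthetic Cheng-style upper-airway section
table ship as versioned fixture CSVs with recorded SHA-256 checksums; the
generators reproduce them bit-for-bit.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .morphometry import (
    MORPHOMETRY_COLUMNS,
    BifurcationSpec,
    StructuralError,
    TracheaSpec,
    build_tree,
    build_upper_airway,
)
from .flow_network import OutletBC, lobar_flow_fractions, solve_steady

#: paper-grade lobar ventilation partition used to calibrate the fixture
DEFAULT_LOBAR_FRACTIONS = {"RUL": 0.19, "RML": 0.09, "RLL": 0.29, "LUL": 0.26, "LLL": 0.17}

#: subtree roots of the five lobes in the canonical binary id scheme
#: (root "b"; children append "0" = right-hand, "1" = left-hand)
DEFAULT_LOBAR_MAP = {"RUL": "b00", "RML": "b010", "RLL": "b011", "LUL": "b10", "LLL": "b11"}

CHARACTERISTIC_FIXTURE = "characteristic_tree_v1.csv"
UPPER_AIRWAY_FIXTURE = "upper_airway_sections_v1.csv"


@dataclass
class TreeRecipe:
    max_generation: int = 6
    mode: str = "characteristic_asymmetric"  # or "weibel_symmetric"
    x_n: float = 3.0
    trachea: TracheaSpec = field(default_factory=TracheaSpec)
    lobar_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LOBAR_MAP))
    lobar_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOBAR_FRACTIONS))
    asymmetry: float = 0.08  # within-lobe daughter conductance-share jitter
    length_ratio: float = 3.0  # branch length / diameter
    right_main_length: float = 2.2  # cm
    left_main_length: float = 5.0  # cm
    branching_half_angle: float = 35.0  # degrees
    seed: int = 20210113

    def __post_init__(self) -> None:
        if self.mode not in ("weibel_symmetric", "characteristic_asymmetric"):
            raise ValueError(f"unknown recipe mode {self.mode!r}")
        if self.max_generation < 0:
            raise ValueError("max_generation must be >= 0")


# ---------------------------------------------------------------------------
# topology and orientation
# ---------------------------------------------------------------------------

def _child_ids(bid: str) -> tuple[str, str]:
    return bid + "0", bid + "1"


def _all_ids(max_generation: int) -> list[str]:
    ids = ["b"]
    frontier = ["b"]
    for _ in range(max_generation):
        nxt = []
        for bid in frontier:
            nxt.extend(_child_ids(bid))
        ids.extend(nxt)
        frontier = nxt
    return ids


def _lobe_of(bid: str, lobar_map: dict[str, str]) -> str:
    for lobe, prefix in lobar_map.items():
        if bid.startswith(prefix):
            return lobe
    return "none"


def _direction(bid: str, parent_dir: np.ndarray, half_angle: float) -> np.ndarray:
    """Deterministic daughter direction: branching plane rotates with depth."""
    gen = len(bid) - 1
    sign = 1.0 if bid.endswith("0") else -1.0
    ref = np.array([1.0, 0.0, 0.0]) if gen % 2 == 1 else np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, parent_dir) * parent_dir
    n = np.linalg.norm(v)
    if n < 1e-12:
        v = np.array([0.0, 1.0, 0.0])
        v = v - np.dot(v, parent_dir) * parent_dir
        n = np.linalg.norm(v)
    v /= n
    th = math.radians(half_angle)
    d = math.cos(th) * parent_dir + sign * math.sin(th) * v
    return d / np.linalg.norm(d)


def _directions(recipe: TreeRecipe) -> dict[str, np.ndarray]:
    dirs: dict[str, np.ndarray] = {"b": np.array([0.0, 0.0, -1.0])}
    for bid in _all_ids(recipe.max_generation):
        if bid == "b":
            continue
        if bid == "b0":  # right main bronchus, toward +x
            th = math.radians(35.0)
            dirs[bid] = np.array([math.sin(th), 0.0, -math.cos(th)])
        elif bid == "b1":  # left main bronchus, toward -x, wider angle
            th = math.radians(45.0)
            dirs[bid] = np.array([-math.sin(th), 0.0, -math.cos(th)])
        else:
            dirs[bid] = _direction(bid, dirs[bid[:-1]], recipe.branching_half_angle)
    return dirs


def _region_of(gen: int) -> str:
    return {0: "trachea", 1: "bif1", 2: "bif2", 3: "bif3"}.get(gen, "peripheral")


def _assemble_table(recipe: TreeRecipe, diameters: dict[str, float], lengths: dict[str, float]) -> pd.DataFrame:
    dirs = _directions(recipe)
    rows = []
    for bid in _all_ids(recipe.max_generation):
        gen = len(bid) - 1
        terminal = gen == recipe.max_generation
        lobe = _lobe_of(bid, recipe.lobar_map) if terminal else _lobe_of(bid, recipe.lobar_map)
        d = dirs[bid]
        rows.append(
            {
                "id": bid,
                "parent_id": "" if bid == "b" else bid[:-1],
                "generation": gen,
                "length_cm": lengths[bid],
                "diameter_cm": diameters[bid],
                "dx": d[0],
                "dy": d[1],
                "dz": d[2],
                "lobe": lobe if lobe != "none" or not terminal else "none",
                "region": _region_of(gen),
            }
        )
    return pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)


# ---------------------------------------------------------------------------
# symmetric (Weibel-style) table
# ---------------------------------------------------------------------------

def make_weibel_table(recipe: TreeRecipe | None = None) -> pd.DataFrame:
    """Fully symmetric binary tree; diameters follow d_child = d_parent * 2^(-1/x_n)."""
    recipe = recipe or TreeRecipe(mode="weibel_symmetric")
    ratio = 2.0 ** (-1.0 / recipe.x_n)
    diameters: dict[str, float] = {}
    lengths: dict[str, float] = {}
    for bid in _all_ids(recipe.max_generation):
        gen = len(bid) - 1
        d = recipe.trachea.diameter * ratio**gen
        diameters[bid] = d
        lengths[bid] = recipe.trachea.length if gen == 0 else recipe.length_ratio * d
    if recipe.max_generation < 4:
        # too shallow for the five-lobe map: label every terminal with one lobe
        recipe = TreeRecipe(**{**recipe.__dict__, "lobar_map": {"RLL": "b"}})
    return _assemble_table(recipe, diameters, lengths)


# ---------------------------------------------------------------------------
# characteristic asymmetric table
# ---------------------------------------------------------------------------

def _within_lobe_shares(recipe: TreeRecipe) -> dict[str, float]:
    """Deterministic (seeded) conductance share of the '0' daughter at each
    within-lobe bifurcation; 0.5 everywhere when asymmetry == 0."""
    rng = np.random.default_rng(recipe.seed)
    shares: dict[str, float] = {}
    roots = set(recipe.lobar_map.values())
    for bid in _all_ids(recipe.max_generation):
        gen = len(bid) - 1
        if gen == recipe.max_generation:
            continue
        inside = any(bid.startswith(p) for p in roots)
        if inside:
            shares[bid] = 0.5 + recipe.asymmetry * float(rng.uniform(-1.0, 1.0))
        else:
            shares[bid] = 0.5
    return shares


def _characteristic_diameters(recipe: TreeRecipe, lobe_root_d: dict[str, float]) -> dict[str, float]:
    """Murray-exact diameters from lobar-root diameters, rescaled so the
    trachea matches the recipe's tracheal diameter exactly."""
    x = recipe.x_n
    shares = _within_lobe_shares(recipe)
    diameters: dict[str, float] = {}
    # descend inside each lobe from its root
    for lobe, root in recipe.lobar_map.items():
        diameters[root] = lobe_root_d[lobe]
        stack = [root]
        while stack:
            bid = stack.pop()
            if len(bid) - 1 == recipe.max_generation:
                continue
            s = shares[bid]
            c0, c1 = _child_ids(bid)
            diameters[c0] = diameters[bid] * s ** (1.0 / x)
            diameters[c1] = diameters[bid] * (1.0 - s) ** (1.0 / x)
            stack.extend([c0, c1])
    # combine upward outside the lobes (Murray combination, exact closure)
    for bid in sorted(
        (b for b in _all_ids(recipe.max_generation) if b not in diameters),
        key=len,
        reverse=True,
    ):
        c0, c1 = _child_ids(bid)
        diameters[bid] = (diameters[c0] ** x + diameters[c1] ** x) ** (1.0 / x)
    scale = recipe.trachea.diameter / diameters["b"]
    return {bid: d * scale for bid, d in diameters.items()}


def _characteristic_lengths(recipe: TreeRecipe, diameters: dict[str, float]) -> dict[str, float]:
    lengths = {}
    for bid, d in diameters.items():
        if bid == "b":
            lengths[bid] = recipe.trachea.length
        elif bid == "b0":
            lengths[bid] = recipe.right_main_length
        elif bid == "b1":
            lengths[bid] = recipe.left_main_length
        else:
            lengths[bid] = recipe.length_ratio * d
    return lengths


def make_characteristic_table(recipe: TreeRecipe | None = None, n_iter: int = 60) -> pd.DataFrame:
    """Five-lobed asymmetric tree calibrated to the physiological lobar split.

    The five lobar-root diameters are the only free parameters; a damped
    fixed-point iteration rescales each by (target/achieved)^(1/4) (laminar
    conductance ~ d^4) until the equal-outlet-pressure flow split matches the
    recipe's lobar fractions.  Entirely deterministic for a given recipe.
    """
    recipe = recipe or TreeRecipe()
    if recipe.max_generation < 4:
        raise StructuralError("characteristic mode requires max_generation >= 4")
    terminals = [b for b in _all_ids(recipe.max_generation) if len(b) - 1 == recipe.max_generation]
    uncovered = [t for t in terminals if _lobe_of(t, recipe.lobar_map) == "none"]
    if uncovered:
        raise StructuralError(f"lobar_map leaves terminals uncovered, e.g. {uncovered[0]!r}")

    lobe_root_d = {lobe: 0.7 for lobe in recipe.lobar_map}
    bc = OutletBC(mode="equal_pressure")
    table = None
    for _ in range(n_iter):
        diameters = _characteristic_diameters(recipe, lobe_root_d)
        lengths = _characteristic_lengths(recipe, diameters)
        table = _assemble_table(recipe, diameters, lengths)
        tree = build_tree(table, BifurcationSpec(x_n=recipe.x_n), trachea=recipe.trachea)
        sol = solve_steady(tree, 6.0, bc=bc)
        achieved = lobar_flow_fractions(tree, sol)
        err = 0.0
        for lobe, target in recipe.lobar_fractions.items():
            ratio = target / achieved[lobe]
            lobe_root_d[lobe] *= ratio ** (0.8 / 4.0)
            err = max(err, abs(achieved[lobe] - target))
        if err < 1e-12:
            break
    return table


# ---------------------------------------------------------------------------
# upper-airway section fixture (synthetic Cheng-style dimensions)
# ---------------------------------------------------------------------------

def make_upper_airway_table() -> pd.DataFrame:
    """Synthetic Cheng-style elliptical section table (unscaled).

    Cross-sectional-area anchors: oral cavity 2.98 cm^2, pharynx 0.95 cm^2,
    glottis/larynx 0.64 cm^2 (the upper-airway minimum); 2:1 ellipse aspect
    ratio, section lengths 7/6/3 cm, and a 1.90 cm equivalent tracheal-end
    diameter of the source cast (used only to derive the fit-to-trachea scale
    factor).  This emulates the literature cast dimensions; it is not a copy
    of any measured table.
    """
    def axes(csa: float, aspect: float = 2.0) -> tuple[float, float]:
        b = math.sqrt(csa / (math.pi * aspect))
        return aspect * b, b

    rows = []
    for name, csa, length in (("oral_cavity", 2.98, 7.0), ("pharynx", 0.95, 6.0), ("larynx", 0.64, 3.0)):
        a, b = axes(csa)
        rows.append({"name": name, "semi_axis_a_cm": a, "semi_axis_b_cm": b, "length_cm": length})
    rows.append({"name": "trachea_end", "semi_axis_a_cm": 0.95, "semi_axis_b_cm": 0.95, "length_cm": 0.0})
    return pd.DataFrame(rows, columns=["name", "semi_axis_a_cm", "semi_axis_b_cm", "length_cm"])


# ---------------------------------------------------------------------------
# injections
# ---------------------------------------------------------------------------

def make_injection(n: int = 2720, disk_diameter: float = 2.16, t_inj: float = 0.0, seed: int = 0):
    """Uniformly distributed particle positions on the oral inlet disk (cm)."""
    from .aerosol import InjectionSet

    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    R = disk_diameter / 2.0
    r = R * np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * math.pi, n)
    positions = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return InjectionSet(n_particles=n, disk_diameter=disk_diameter, t_inj=t_inj, positions=positions, seed=seed)


# ---------------------------------------------------------------------------
# perturbation fixtures
# ---------------------------------------------------------------------------

def perturb_morphometry(table: pd.DataFrame, cv: float, seed: int = 0) -> pd.DataFrame:
    """Multiplicative lognormal noise (coefficient of variation cv) on
    lengths and diameters; cv = 0 is the identity; positivity preserved by
    construction of the lognormal."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    out = table.copy()
    if cv == 0:
        return out
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma  # unit mean
    rng = np.random.default_rng(seed)
    n = len(out)
    out["length_cm"] = out["length_cm"] * np.exp(rng.normal(mu, sigma, n))
    out["diameter_cm"] = out["diameter_cm"] * np.exp(rng.normal(mu, sigma, n))
    return out


# ---------------------------------------------------------------------------
# fixture files (content-addressed)
# ---------------------------------------------------------------------------

def _csv_bytes(table: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    table.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
    return buf.getvalue().encode()


def fixture_checksum(table: pd.DataFrame) -> str:
    return hashlib.sha256(_csv_bytes(table)).hexdigest()


def _fixture_path(name: str):
    return resources.files("airwaysim").joinpath("fixtures", name)


def load_fixture_table(name: str) -> pd.DataFrame:
    with _fixture_path(name).open("rb") as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[])


def load_characteristic_table() -> pd.DataFrame:
    """The packaged, calibrated characteristic morphometry table."""
    t = load_fixture_table(CHARACTERISTIC_FIXTURE)
    t["parent_id"] = t["parent_id"].replace("", np.nan)
    return t


def load_upper_airway_table() -> pd.DataFrame:
    return load_fixture_table(UPPER_AIRWAY_FIXTURE)


def default_tree(trachea: TracheaSpec | None = None, bif_spec: BifurcationSpec | None = None):
    """Build the packaged characteristic airway model (tree + scaled upper airway)."""
    trachea = trachea or TracheaSpec()
    upper = build_upper_airway(load_upper_airway_table(), trachea)
    return build_tree(load_characteristic_table(), bif_spec, trachea=trachea, upper_airway=upper)


def write_fixtures(directory) -> dict[str, str]:
    """Regenerate the packaged fixture CSVs and their checksum record."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        CHARACTERISTIC_FIXTURE: make_characteristic_table(),
        UPPER_AIRWAY_FIXTURE: make_upper_airway_table(),
    }
    checksums = {}
    for name, table in tables.items():
        data = _csv_bytes(table)
        (directory / name).write_bytes(data)
        checksums[name] = hashlib.sha256(data).hexdigest()
    (directory / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True) + "\n")
    return checksums


def load_checksums() -> dict[str, str]:
    with _fixture_path("checksums.json").open("r") as fh:
        return json.load(fh)
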