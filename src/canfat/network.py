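"""Idealized 2-D cortical cross-sections and bone-cell network topology.

The cortex is modeled as an elliptical annulus (periosteal ellipse outside,
endocortical ellipse inside) tiled into sub-sectors.  Osteocytes are seeded
inside the cortex by non-overlapping rejection sampling with counts
proportional to sub-sector area; a single layer of surface precursor cells
sits on each boundary at equal-angle sectors.  Cells are functionally
coupled (able to pass Ca2+) when their separation is within a canalicular
length; immediately adjacent same-surface precursors are always coupled.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Default canalicular coupling radius, um.
CANALICULAR_RADIUS = 50.0
#: Default minimal osteocyte-osteocyte separation, um.
MIN_SEPARATION = 15.0
#: Osteocyte lacunar densities (cells/mm^2) measured in young-adult and
#: senescent murine tibia mid-shaft cortices.
DENSITY = {"young": 626.0, "aged": 940.0}


class GeometryError(ValueError):
    pass


class SeedingError(RuntimeError):
    pass


class NetworkParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class CrossSectionGeometry:
    """Elliptical-annulus cortex: semi-axes in um, area in mm^2."""

    outer_a: float = 600.0
    outer_b: float = 450.0
    inner_a: float = 450.0
    inner_b: float = 320.0
    n_subsectors: int = 384
    n_surface_sectors: int = 96

    def __post_init__(self):
        if not (self.outer_a > self.inner_a > 0 and self.outer_b > self.inner_b > 0):
            raise GeometryError(
                "endocortical ellipse must lie strictly inside the periosteal one "
                f"(outer {self.outer_a}x{self.outer_b}, inner {self.inner_a}x{self.inner_b})"
            )
        if self.n_subsectors <= 0 or self.n_surface_sectors <= 0:
            raise GeometryError("sector counts must be positive")
        if self.n_subsectors % self.n_surface_sectors != 0:
            raise GeometryError(
                "n_subsectors must be a multiple of n_surface_sectors "
                "(angular wedges split into radial bands)"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (0.0, 0.0)

    @property
    def cortical_area_mm2(self) -> float:
        """Area of the annulus, mm^2."""
        um2 = math.pi * (self.outer_a * self.outer_b - self.inner_a * self.inner_b)
        return um2 * 1e-6

    @property
    def n_radial_bands(self) -> int:
        return self.n_subsectors // self.n_surface_sectors

    # The annulus is parameterized by (s, phi): s in [0,1] interpolates
    # radially from the inner to the outer ellipse, phi is the angle.
    def point(self, s: float | np.ndarray, phi: float | np.ndarray):
        a = self.inner_a + (self.outer_a - self.inner_a) * np.asarray(s)
        b = self.inner_b + (self.outer_b - self.inner_b) * np.asarray(s)
        return a * np.cos(phi), b * np.sin(phi)

    def _jacobian(self, s, phi):
        da, db = self.outer_a - self.inner_a, self.outer_b - self.inner_b
        a = self.inner_a + da * s
        b = self.inner_b + db * s
        return da * b * np.cos(phi) ** 2 + a * db * np.sin(phi) ** 2

    def subsector_bounds(self, k: int) -> tuple[float, float, float, float]:
        """(s_lo, s_hi, phi_lo, phi_hi) of sub-sector ``k``.

        Sub-sectors are numbered angular-wedge major: wedge ``k // bands``,
        radial band ``k % bands`` counted from the endocortical side.
        """
        bands = self.n_radial_bands
        wedge, band = divmod(k, bands)
        dphi = 2 * math.pi / self.n_surface_sectors
        return (band / bands, (band + 1) / bands, wedge * dphi, (wedge + 1) * dphi)

    def subsector_area_um2(self, k: int) -> float:
        """Exact area of sub-sector ``k`` (integral of the Jacobian)."""
        s0, s1, p0, p1 = self.subsector_bounds(k)
        da, db = self.outer_a - self.inner_a, self.outer_b - self.inner_b
        # int a(s) ds and int b(s) ds over [s0, s1]
        int_a = self.inner_a * (s1 - s0) + da * (s1**2 - s0**2) / 2
        int_b = self.inner_b * (s1 - s0) + db * (s1**2 - s0**2) / 2
        int_cos2 = (p1 - p0) / 2 + (math.sin(2 * p1) - math.sin(2 * p0)) / 4
        int_sin2 = (p1 - p0) / 2 - (math.sin(2 * p1) - math.sin(2 * p0)) / 4
        return da * int_b * int_cos2 + db * int_a * int_sin2

    def subsector_of(self, s: float, phi: float) -> int:
        bands = self.n_radial_bands
        wedge = int((phi % (2 * math.pi)) / (2 * math.pi) * self.n_surface_sectors)
        wedge = min(wedge, self.n_surface_sectors - 1)
        band = min(int(s * bands), bands - 1)
        return wedge * bands + band

    def to_dict(self) -> dict:
        return {
            "outer_a": self.outer_a, "outer_b": self.outer_b,
            "inner_a": self.inner_a, "inner_b": self.inner_b,
            "n_subsectors": self.n_subsectors,
            "n_surface_sectors": self.n_surface_sectors,
        }


@dataclass(frozen=True)
class Cell:
    id: int
    kind: str                 # "osteocyte" | "precursor"
    x: float                  # um
    y: float                  # um
    surface: str              # "periosteal" | "endocortical" | "none"
    sector: int               # sub-sector id (osteocytes) or surface sector


@dataclass
class CellNetwork:
    geometry: CrossSectionGeometry
    cells: list[Cell]
    adjacency: set[tuple[int, int]]   # unordered pairs stored as (min, max)
    age_class: str = "young"
    rng_seed: int = 0

    def __post_init__(self):
        ids = {c.id for c in self.cells}
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"self-edge on cell {a}")
            if a not in ids or b not in ids:
                raise ValueError(f"edge ({a},{b}) references unknown cell id")

    @property
    def osteocytes(self) -> list[Cell]:
        return [c for c in self.cells if c.kind == "osteocyte"]

    @property
    def precursors(self) -> list[Cell]:
        return [c for c in self.cells if c.kind == "precursor"]

    def positions(self) -> np.ndarray:
        return np.array([[c.x, c.y] for c in self.cells], dtype=float)

    def degree(self, cell_id: int) -> int:
        return sum(1 for a, b in self.adjacency if a == cell_id or b == cell_id)


@dataclass(frozen=True)
class NetworkSummary:
    osteocyte_density_mm2: float
    periosteal_precursor_connections: tuple[float, float]   # mean, sd
    osteocyte_connections: tuple[float, float]              # mean, sd
    connection_length_um: tuple[float, float] | None        # mean, sd; None if no edges
    n_cells: int
    n_edges: int


def build_geometry(**config) -> CrossSectionGeometry:
    """Build a tiled elliptical-annulus cross-section geometry."""
    return CrossSectionGeometry(**config)


def seed_osteocytes(
    geometry: CrossSectionGeometry,
    density_mm2: float,
    min_separation: float = MIN_SEPARATION,
    seed: int = 0,
    max_tries: int = 400,
) -> list[Cell]:
    """Seed osteocytes by a non-overlapping rejection ("random walk") process.

    The expected total count is ``density x cortical area``, allocated to
    sub-sectors proportional to their exact areas (fractional parts resolved
    by seeded stochastic rounding so the expectation is unbiased).  Within a
    sub-sector, positions are sampled uniformly by area and rejected if
    closer than ``min_separation`` to any previously placed osteocyte.
    """
    if density_mm2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    cells: list[Cell] = []
    placed = np.empty((0, 2))
    for k in range(geometry.n_subsectors):
        expected = density_mm2 * geometry.subsector_area_um2(k) * 1e-6
        n_k = int(np.floor(expected))
        if rng.random() < expected - n_k:
            n_k += 1
        s0, s1, p0, p1 = geometry.subsector_bounds(k)
        # Jacobian is linear in s and sinusoidal in phi; corner/midpoint
        # scan with a safety margin dominates it on the patch.
        jmax = 1.05 * max(
            float(geometry._jacobian(s, p))
            for s in (s0, s1) for p in (p0, (p0 + p1) / 2, p1)
        )
        for _ in range(n_k):
            for attempt in range(max_tries):
                s = rng.uniform(s0, s1)
                phi = rng.uniform(p0, p1)
                if rng.random() * jmax > geometry._jacobian(s, phi):
                    continue  # not uniform-by-area yet
                if s <= 0.0 or s >= 1.0:
                    continue  # strictly interior
                x, y = geometry.point(s, phi)
                if placed.size:
                    d2 = np.min(np.sum((placed - (x, y)) ** 2, axis=1))
                    if d2 < min_separation**2:
                        continue
                cells.append(Cell(len(cells), "osteocyte", float(x), float(y), "none", k))
                placed = np.vstack([placed, [x, y]])
                break
            else:
                raise SeedingError(
                    f"could not place osteocyte in sub-sector {k} at density "
                    f"{density_mm2}/mm^2 with min separation {min_separation} um"
                )
    return cells


def place_precursors(geometry: CrossSectionGeometry, id_offset: int = 0) -> list[Cell]:
    """One precursor per equal-angle surface sector on each boundary."""
    cells: list[Cell] = []
    n = geometry.n_surface_sectors
    angles = 2 * math.pi * (np.arange(n) + 0.5) / n
    next_id = id_offset
    for surface, (a, b) in (
        ("periosteal", (geometry.outer_a, geometry.outer_b)),
        ("endocortical", (geometry.inner_a, geometry.inner_b)),
    ):
        for sec, phi in enumerate(angles):
            cells.append(
                Cell(next_id, "precursor",
                     float(a * math.cos(phi)), float(b * math.sin(phi)),
                     surface, sec)
            )
            next_id += 1
    return cells


def build_adjacency(
    cells: list[Cell], canalicular_radius: float = CANALICULAR_RADIUS
) -> set[tuple[int, int]]:
    """Functional-coupling edges.

    Osteocyte-osteocyte and osteocyte-precursor pairs couple when separated
    by at most the canalicular radius.  Precursor-precursor coupling exists
    only between immediately adjacent precursors of the same surface (a
    closed ring per surface); no distance rule applies between precursors.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    edges: set[tuple[int, int]] = set()
    # ring edges per surface
    for surface in ("periosteal", "endocortical"):
        ring = sorted((c for c in cells if c.kind == "precursor" and c.surface == surface),
                      key=lambda c: c.sector)
        m = len(ring)
        if m >= 2:
            for i in range(m):
                a, b = ring[i].id, ring[(i + 1) % m].id
                if a != b:
                    edges.add((min(a, b), max(a, b)))
    # distance edges involving at least one osteocyte
    pos = np.array([[c.x, c.y] for c in cells])
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(canalicular_radius):
        ci, cj = cells[i], cells[j]
        if ci.kind == "precursor" and cj.kind == "precursor":
            continue
        edges.add((min(ci.id, cj.id), max(ci.id, cj.id)))
    return edges


def generate_network(
    geometry: CrossSectionGeometry | None = None,
    age_class: str = "young",
    density_mm2: float | None = None,
    min_separation: float = MIN_SEPARATION,
    canalicular_radius: float = CANALICULAR_RADIUS,
    seed: int = 0,
) -> CellNetwork:
    """Generate a full cell network for one cross-section."""
    geometry = geometry or CrossSectionGeometry()
    if density_mm2 is None:
        density_mm2 = DENSITY[age_class]
    osteo = seed_osteocytes(geometry, density_mm2, min_separation, seed)
    prec = place_precursors(geometry, id_offset=len(osteo))
    cells = osteo + prec
    adjacency = build_adjacency(cells, canalicular_radius)
    return CellNetwork(geometry, cells, adjacency, age_class, seed)


def summarize_network(network: CellNetwork) -> NetworkSummary:
    if not network.cells:
        raise ValueError("cannot summarize an empty network")
    area = network.geometry.cortical_area_mm2
    n_osteo = len(network.osteocytes)
    deg: dict[int, int] = {c.id: 0 for c in network.cells}
    lengths = []
    by_id = {c.id: c for c in network.cells}
    for a, b in network.adjacency:
        deg[a] += 1
        deg[b] += 1
        ca, cb = by_id[a], by_id[b]
        lengths.append(math.hypot(ca.x - cb.x, ca.y - cb.y))
    pp = [deg[c.id] for c in network.precursors if c.surface == "periosteal"]
    oo = [deg[c.id] for c in network.osteocytes]

    def _ms(v):
        if not v:
            return (0.0, 0.0)
        arr = np.asarray(v, dtype=float)
        return (float(arr.mean()), float(arr.std()))

    return NetworkSummary(
        osteocyte_density_mm2=n_osteo / area,
        periosteal_precursor_connections=_ms(pp),
        osteocyte_connections=_ms(oo),
        connection_length_um=_ms(lengths) if lengths else None,
        n_cells=len(network.cells),
        n_edges=len(network.adjacency),
    )


# ---------------------------------------------------------------------------
# plain-text serialization: structured header + cell table + edge table

def write_network(network: CellNetwork, path) -> None:
    buf = io.StringIO()
    g = network.geometry
    buf.write("# canfat cell network v1\n")
    for k, v in g.to_dict().items():
        buf.write(f"# geometry.{k} = {v!r}\n")
    buf.write(f"# age_class = {network.age_class}\n")
    buf.write(f"# rng_seed = {network.rng_seed}\n")
    buf.write("[cells]\n")
    buf.write("id,kind,x_um,y_um,surface,sector\n")
    for c in network.cells:
        buf.write(f"{c.id},{c.kind},{c.x:.17g},{c.y:.17g},{c.surface},{c.sector}\n")
    buf.write("[edges]\n")
    buf.write("id_a,id_b\n")
    for a, b in sorted(network.adjacency):
        buf.write(f"{a},{b}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_network(path) -> CellNetwork:
    geom_cfg: dict = {}
    meta = {"age_class": "young", "rng_seed": 0}
    cells: list[Cell] = []
    adjacency: set[tuple[int, int]] = set()
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key.startswith("geometry."):
                        name = key[len("geometry."):]
                        geom_cfg[name] = (
                            int(val) if name.startswith("n_") else float(val)
                        )
                    elif key == "age_class":
                        meta["age_class"] = val
                    elif key == "rng_seed":
                        meta["rng_seed"] = int(val)
                continue
            if line in ("[cells]", "[edges]"):
                section = line
                continue
            if line.startswith("id"):
                continue  # column header
            parts = line.split(",")
            try:
                if section == "[cells]":
                    cells.append(Cell(int(parts[0]), parts[1], float(parts[2]),
                                      float(parts[3]), parts[4], int(parts[5])))
                elif section == "[edges]":
                    a, b = int(parts[0]), int(parts[1])
                    adjacency.add((min(a, b), max(a, b)))
                else:
                    raise NetworkParseError("data outside any section", lineno)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, NetworkParseError):
                    raise
                raise NetworkParseError(f"malformed row: {line!r}", lineno) from exc
    if not geom_cfg:
        raise NetworkParseError("missing geometry header")
    geometry = CrossSectionGeometry(**geom_cfg)
    try:
        return CellNetwork(geometry, cells, adjacency, **meta)
    except ValueError as exc:
        raise NetworkParseError(str(exc)) from exc
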