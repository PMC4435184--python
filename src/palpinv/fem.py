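"""Forward model: linear-elasticity FEM of a probe indenting tissue with a
stiff spherical inclusion, plus the three probe-deformation features.

Geometry and physics
--------------------
A soft tissue slab (default 120 x 120 x 20 mm, E = 5 kPa, nu = 0.49) rests on
a rigid base.  A square deformable probe block (default 25 x 25 x 5 mm,
30 kPa, emulating the soft optical sensing layer) sits on the tissue surface,
centred over a stiff spherical inclusion
of diameter ``d`` whose top lies ``h`` mm below the surface.  The probe top is
displaced downward by a prescribed indentation; the probe bottom couples to
the tissue surface vertically while sliding freely laterally (a frictionless
tied contact, valid for monotone indentation without lift-off).  The solved
field of interest is the probe-bottom *relative* vertical displacement
``w = u_z + indent``: how far each point of the probe's bottom face is pushed
up into the probe relative to the probe top's rigid travel.  Over a stiff
obstruction the probe compresses more, so ``w`` is larger.

Discretization
--------------
Structured axis-aligned trilinear hexahedra on a graded grid: uniform fine
spacing (default 1 mm) over the inclusion and contact region, geometrically
growing cells toward the far tissue boundary.  The probe footprint edge is
always a grid line.  Near-incompressibility is handled by selective reduced
integration of the volumetric term (see ``_element``).  By default the mesh
models one quarter of the domain with symmetry planes through the probe axis
(the inclusion is always on-axis) and mirrors the solved probe-bottom field;
``symmetry=False`` builds the full mesh.

Features
--------
``quantify_deformation`` reduces the field to the tactile feature triple:
maximum deformation (mm), total deformation (mm, grid sum), and deformation
area (mm^2, thresholded cell count).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from ._element import box_stiffness_parts, lame
from .phantom import InclusionScenario

__all__ = [
    "FemConfig",
    "FemModel",
    "DeformationField",
    "FeatureTriple",
    "build_model",
    "solve_indentation",
    "solve_displacements",
    "quantify_deformation",
    "forward",
    "forward_features",
    "uniaxial_slab_model",
    "write_mesh",
    "read_mesh",
]


@dataclass(frozen=True)
class FemConfig:
    """Mesh-density and loading controls for the forward model.

    fine_h : uniform element size (mm) in the refined central region and in z.
    refine : integer subdivision factor applied to every grid interval
        (refine=2 halves every element edge: a full mesh doubling).
    indent_mm : prescribed downward travel of the probe top.
    detect_floor_mm : optical detectability floor; excess deformation below
        this value (default 2 um) is treated as unobservable and zeroed in the
        forward field, emulating that sub-threshold waveguide deformation
        scatters no measurable light.
    area_eps_mm : displacement threshold for the deformation-area feature
        (default 10 um), the deformation needed to light up a blob pixel.
    symmetry : solve a quarter model with mirror planes through the probe axis
        (valid because scenarios place the inclusion on-axis).
    confine_sides : constrain lateral normal displacement on the slab sides
        (used by uniaxial verification problems; default free sides).
    """

    fine_h: float = 1.0
    fine_extent: float = 8.0
    refine: int = 1
    probe_modulus_kpa: float = 30.0
    probe_nu: float = 0.49
    probe_height_mm: float = 5.0
    probe_nz: int = 2
    indent_mm: float = 2.0
    detect_floor_mm: float = 2e-3
    area_eps_mm: float = 1e-2
    grid_n: int = 26
    solver: str = "auto"  # "auto" (CG with direct fallback), "cg", "direct"
    symmetry: bool = True
    confine_sides: bool = False
    growth: float = 1.7
    max_probe_spacing: float = 2.5

    def __post_init__(self) -> None:
        if self.fine_h <= 0 or self.refine < 1 or self.probe_nz < 1:
            raise ValueError("invalid mesh controls")
        if self.indent_mm <= 0:
            raise ValueError("indent_mm must be positive")


@dataclass
class FemModel:
    """Assembled-geometry container: mesh, materials, constraint bookkeeping."""

    nodes: np.ndarray  # (N, 3) coordinates, mm
    elements: np.ndarray  # (M, 8) node ids
    E: np.ndarray  # (M,) kPa
    nu: np.ndarray  # (M,)
    region: np.ndarray  # (M,) 0=tissue 1=inclusion 2=probe
    dims: np.ndarray  # (M, 3) element edge lengths
    ties: np.ndarray  # (T, 2) [slave_dof, master_dof]
    bcs: list  # [(dof array, value per unit indent)]
    pb_nodes: np.ndarray  # probe-bottom node-id grid, shape (ny, nx)
    pb_x: np.ndarray
    pb_y: np.ndarray
    symmetry: bool
    scenario: InclusionScenario | None = None
    config: FemConfig | None = None

    @property
    def ndof(self) -> int:
        return 3 * len(self.nodes)

    def validate(self) -> None:
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise ValueError("element references node out of range")
        if not np.all(self.dims > 0):
            raise ValueError("non-positive element volume")
        if not np.all(self.E > 0):
            raise ValueError("non-positive Young's modulus")


@dataclass
class DeformationField:
    """Vertical relative displacement of the probe bottom on a regular grid.

    ``w[i, j]`` is the displacement (mm) at ``(y[i], x[j])``; positive values
    mean the probe bottom is pushed up into the probe.
    """

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.y), len(self.x)):
            raise ValueError("w shape must be (len(y), len(x))")
        if self.w.size == 0:
            raise ValueError("empty deformation grid")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite deformation values")

    @property
    def cell_area(self) -> float:
        dx = (self.x[-1] - self.x[0]) / max(len(self.x) - 1, 1)
        dy = (self.y[-1] - self.y[0]) / max(len(self.y) - 1, 1)
        return abs(dx * dy)


@dataclass(frozen=True)
class FeatureTriple:
    """(maximum, total, area) deformation features in FEM or pixel units."""

    f1: float
    f2: float
    f3: float
    unit_system: str = "FEM"

    def __post_init__(self) -> None:
        if self.unit_system not in ("FEM", "TSIS"):
            raise ValueError("unit_system must be 'FEM' or 'TSIS'")
        if not all(np.isfinite([self.f1, self.f2, self.f3])):
            raise ValueError("non-finite feature value")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


# ---------------------------------------------------------------------------
# mesh construction


def _half_lateral_lines(cfg: FemConfig, fine_r: float, probe_half: float, domain_half: float) -> np.ndarray:
    """Grid lines from the probe axis (0) to the far boundary (domain_half).

    Uniform ``fine_h`` spacing out to ``fine_r``, growth-limited cells under
    the probe (spacing capped at ``max_probe_spacing``), free geometric growth
    beyond the probe edge.  ``probe_half`` and ``domain_half`` are always
    included exactly.
    """
    h = cfg.fine_h
    fine_r = min(max(fine_r, 2 * h), probe_half)
    n_fine = max(int(round(fine_r / h)), 1)
    lines = list(np.linspace(0.0, n_fine * h, n_fine + 1))
    s = h
    x = lines[-1]
    while True:
        s = min(s * cfg.growth, cfg.max_probe_spacing)
        if x + s >= probe_half - 0.4 * s:
            break
        x += s
        lines.append(x)
    if probe_half > lines[-1] + 1e-9:
        lines.append(probe_half)
    x = lines[-1]
    while domain_half > x + 1e-9:
        s = s * cfg.growth
        if x + s >= domain_half - 0.4 * s:
            break
        x += s
        lines.append(x)
    if domain_half > lines[-1] + 1e-9:
        lines.append(domain_half)
    out = np.array(lines)
    if cfg.refine > 1:
        refined = [out[:1]]
        for a, b in zip(out[:-1], out[1:]):
            refined.append(np.linspace(a, b, cfg.refine + 1)[1:])
        out = np.concatenate(refined)
    return out


def _grid_nodes(xl: np.ndarray, yl: np.ndarray, zl: np.ndarray) -> np.ndarray:
    X, Y, Z = np.meshgrid(xl, yl, zl, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def _grid_elements(nx: int, ny: int, nz: int) -> np.ndarray:
    """Hex connectivity for an (nx, ny, nz)-element structured grid.

    Node id of lattice point (i, j, k) is ``(i*(ny+1) + j)*(nz+1) + k``.
    """

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    conn = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]
    )
    return conn


def _elem_dims(xl, yl, zl) -> np.ndarray:
    dx, dy, dz = np.diff(xl), np.diff(yl), np.diff(zl)
    DX, DY, DZ = np.meshgrid(dx, dy, dz, indexing="ij")
    return np.column_stack([DX.ravel(), DY.ravel(), DZ.ravel()])


def _check_resolution(lines: np.ndarray, lo: float, hi: float, r: float, axis: str) -> None:
    inside = (lines > lo - 1e-9) & (lines < hi + 1e-9)
    idx = np.flatnonzero(inside)
    if len(idx) < 2:
        raise ValueError(
            f"mesh too coarse: fewer than 2 grid lines cross the inclusion along {axis}"
        )
    spac = np.diff(lines)
    lo_i = max(idx[0] - 1, 0)
    hi_i = min(idx[-1], len(spac) - 1)
    if spac[lo_i : hi_i + 1].max() > r + 1e-9:
        raise ValueError(
            f"mesh too coarse along {axis}: element size "
            f"{spac[lo_i:hi_i + 1].max():.3g} mm exceeds half the inclusion diameter "
            f"{r:.3g} mm (need >= 2 elements across the inclusion)"
        )


def build_model(scenario: InclusionScenario, config: FemConfig | None = None) -> FemModel:
    """Mesh a scenario: graded hex grid for tissue + probe block, materials, BCs."""
    cfg = config or FemConfig()
    half = scenario.tissue_side / 2.0
    probe_half = scenario.probe_side / 2.0
    if probe_half > half + 1e-9:
        raise ValueError("probe footprint larger than tissue")
    thick = scenario.tissue_thickness
    r = scenario.d / 2.0
    zc = thick - scenario.h - r  # sphere centre height above base

    # the fine region is scenario-independent (>= the largest inclusion radius)
    # so that every scenario under one config shares an identical mesh
    fine_r = max(cfg.fine_extent, r + cfg.fine_h)
    half_lines = _half_lateral_lines(cfg, fine_r, probe_half, half)
    if cfg.symmetry:
        lat = half_lines
    else:
        lat = np.unique(np.concatenate([-half_lines, half_lines]))
    nz = max(int(round(thick / cfg.fine_h)), 2) * cfg.refine
    zl = np.linspace(0.0, thick, nz + 1)

    # resolution check: >= 2 elements across the inclusion in every axis
    if cfg.symmetry:
        _check_resolution(lat, 0.0, r, r, "x")
    else:
        _check_resolution(lat, -r, r, r, "x")
    _check_resolution(zl, zc - r, zc + r, r, "z")

    xl = yl = lat
    nxl, nyl, nzl = len(xl) - 1, len(yl) - 1, len(zl) - 1
    t_nodes = _grid_nodes(xl, yl, zl)
    t_elems = _grid_elements(nxl, nyl, nzl)
    t_dims = _elem_dims(xl, yl, zl)

    cent = t_nodes[t_elems].mean(axis=1)
    inside = (cent[:, 0] ** 2 + cent[:, 1] ** 2 + (cent[:, 2] - zc) ** 2) <= r * r
    if scenario.E_inc > scenario.E_bg and not inside.any():
        raise ValueError("mesh too coarse: no element centroid falls inside the inclusion")
    E = np.full(len(t_elems), scenario.E_bg)
    E[inside] = scenario.E_inc
    nu = np.full(len(t_elems), scenario.nu)
    region = np.zeros(len(t_elems), dtype=np.int8)
    region[inside] = 1

    # probe block on top of the tissue, footprint edge aligned with grid lines
    p_mask = xl <= probe_half + 1e-9 if cfg.symmetry else np.abs(xl) <= probe_half + 1e-9
    pxl = xl[p_mask]
    pyl = pxl
    pzl = np.linspace(thick, thick + cfg.probe_height_mm, cfg.probe_nz * cfg.refine + 1)
    p_nodes = _grid_nodes(pxl, pyl, pzl)
    p_elems = _grid_elements(len(pxl) - 1, len(pyl) - 1, len(pzl) - 1) + len(t_nodes)
    p_dims = _elem_dims(pxl, pyl, pzl)

    nodes = np.vstack([t_nodes, p_nodes])
    elements = np.vstack([t_elems, p_elems])
    dims = np.vstack([t_dims, p_dims])
    E = np.concatenate([E, np.full(len(p_elems), cfg.probe_modulus_kpa)])
    nu = np.concatenate([nu, np.full(len(p_elems), cfg.probe_nu)])
    region = np.concatenate([region, np.full(len(p_elems), 2, dtype=np.int8)])

    # lattice index helpers
    Nyt, Nzt = len(yl), len(zl)
    Nyp, Nzp = len(pyl), len(pzl)

    def t_id(i, j, k):
        return (i * Nyt + j) * Nzt + k

    def p_id(i, j, k):
        return (i * Nyp + j) * Nzp + k + len(t_nodes)

    # frictionless vertical tie: probe-bottom z dof follows tissue-top z dof
    lat_idx = np.flatnonzero(p_mask)
    ties = []
    pb_grid = np.empty((Nyp, Nyp), dtype=np.int64)
    for a, ia in enumerate(lat_idx):
        for b, jb in enumerate(lat_idx):
            pn = p_id(a, b, 0)
            tn = t_id(ia, jb, Nzt - 1)
            ties.append((3 * pn + 2, 3 * tn + 2))
            pb_grid[b, a] = pn  # pb_grid[y, x]
    ties = np.array(ties, dtype=np.int64)

    # boundary conditions (value = scale * indent)
    bcs: list[tuple[np.ndarray, float]] = []
    base = np.array([t_id(i, j, 0) for i in range(len(xl)) for j in range(len(yl))])
    bcs.append((np.concatenate([3 * base, 3 * base + 1, 3 * base + 2]), 0.0))
    ptop = np.array(
        [p_id(a, b, Nzp - 1) for a in range(len(pxl)) for b in range(len(pyl))]
    )
    bcs.append((np.concatenate([3 * ptop, 3 * ptop + 1]), 0.0))
    bcs.append((3 * ptop + 2, -1.0))
    if cfg.symmetry:
        tx0 = np.flatnonzero(np.isclose(nodes[:, 0], 0.0))
        ty0 = np.flatnonzero(np.isclose(nodes[:, 1], 0.0))
        bcs.append((3 * tx0, 0.0))
        bcs.append((3 * ty0 + 1, 0.0))
    if cfg.confine_sides:
        # normal constraint on the outer side faces, tissue and probe alike
        sx = np.flatnonzero(np.isclose(np.abs(nodes[:, 0]), half))
        sy = np.flatnonzero(np.isclose(np.abs(nodes[:, 1]), half))
        bcs.append((3 * sx, 0.0))
        bcs.append((3 * sy + 1, 0.0))

    model = FemModel(
        nodes=nodes,
        elements=elements,
        E=E,
        nu=nu,
        region=region,
        dims=dims,
        ties=ties,
        bcs=bcs,
        pb_nodes=pb_grid,
        pb_x=pxl.copy(),
        pb_y=pyl.copy(),
        symmetry=cfg.symmetry,
        scenario=scenario,
        config=cfg,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# assembly and solve


def _assemble(model: FemModel) -> sp.csr_matrix:
    """Global stiffness in COO->CSR form, tied dofs merged by index relabeling."""
    dims_key = np.round(model.dims, 9)
    uniq, inv = np.unique(dims_key, axis=0, return_inverse=True)
    k_dev_u, k_vol_u = box_stiffness_parts(uniq)
    lam, mu = lame(model.E, model.nu)
    k_el = lam[:, None, None] * k_vol_u[inv] + mu[:, None, None] * k_dev_u[inv]

    edof = (3 * model.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    dofmap = np.arange(model.ndof)
    if len(model.ties):
        dofmap[model.ties[:, 0]] = model.ties[:, 1]
    edof = dofmap[edof]
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sp.coo_matrix((k_el.ravel(), (rows, cols)), shape=(model.ndof, model.ndof))
    return K.tocsr()


def _fixed_dofs(model: FemModel, indent: float) -> tuple[np.ndarray, np.ndarray]:
    dofmap = np.arange(model.ndof)
    if len(model.ties):
        dofmap[model.ties[:, 0]] = model.ties[:, 1]
    vals: dict[int, float] = {}
    for dofs, scale in model.bcs:
        v = scale * indent
        for d in dofmap[np.asarray(dofs, dtype=np.int64)]:
            vals[int(d)] = v
    fixed = np.array(sorted(vals), dtype=np.int64)
    return fixed, np.array([vals[d] for d in fixed])


def solve_displacements(model: FemModel, indent: float) -> np.ndarray:
    """Nodal displacement array (N, 3) for a prescribed probe-top indentation."""
    if indent <= 0:
        raise ValueError("indent must be positive")
    thick = model.scenario.tissue_thickness if model.scenario else None
    if thick is not None and indent > 0.25 * thick:
        raise ValueError("indent exceeds 25% of tissue thickness (small-strain regime)")
    K = _assemble(model)
    dofmap = np.arange(model.ndof)
    if len(model.ties):
        dofmap[model.ties[:, 0]] = model.ties[:, 1]
    used = np.unique(dofmap)
    fixed, fvals = _fixed_dofs(model, indent)
    free = np.setdiff1d(used, fixed, assume_unique=False)

    Kf = K[free][:, free].tocsc()
    rhs = -K[free][:, fixed] @ fvals
    solver = (model.config.solver if model.config else "auto").lower()
    uf = None
    if solver in ("auto", "cg"):
        diag = Kf.diagonal()
        if np.all(diag > 0):
            M = spla.LinearOperator(Kf.shape, matvec=lambda v, d=1.0 / diag: d * v)
            uf, info = spla.cg(Kf, rhs, rtol=1e-10, atol=0.0, M=M, maxiter=20000)
            if info != 0:
                if solver == "cg":
                    raise RuntimeError(f"CG did not converge (info={info})")
                uf = None
        elif solver == "cg":
            raise RuntimeError("system not positive definite: CG unusable")
    if uf is None:
        try:
            lu = spla.splu(Kf)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise RuntimeError(f"stiffness factorization failed: {exc}") from exc
        uf = lu.solve(rhs)
    if not np.all(np.isfinite(uf)):
        raise RuntimeError("solver produced non-finite displacements")
    res = np.linalg.norm(Kf @ uf - rhs)
    scale = max(np.linalg.norm(rhs), 1e-30)
    if res / scale > 1e-8:
        raise RuntimeError(f"solver did not converge: relative residual {res / scale:.2e}")

    u = np.zeros(model.ndof)
    u[free] = uf
    u[fixed] = fvals
    u = u[dofmap]  # propagate masters to tied slaves
    return u.reshape(-1, 3)


def solve_indentation(
    model: FemModel, indent: float | None = None, grid_n: int | None = None
) -> DeformationField:
    """Solve the indentation problem and extract the probe-bottom field.

    Returns the relative vertical displacement ``w = u_z + indent`` resampled
    onto a regular ``grid_n`` x ``grid_n`` grid over the probe footprint (for
    quarter-symmetric models the solved quadrant is mirrored).
    """
    cfg = model.config or FemConfig()
    indent = cfg.indent_mm if indent is None else indent
    grid_n = cfg.grid_n if grid_n is None else grid_n
    u = solve_displacements(model, indent)
    w_nodes = u[model.pb_nodes, 2] + indent  # (ny, nx) on the probe-bottom lattice
    interp = RegularGridInterpolator(
        (model.pb_y, model.pb_x), w_nodes, method="linear", bounds_error=False, fill_value=None
    )
    half = abs(model.pb_x[-1])
    # cell-centred grid: grid_n^2 cells tile the footprint exactly
    pitch = 2 * half / grid_n
    gx = -half + (np.arange(grid_n) + 0.5) * pitch
    gy = gx.copy()
    GX, GY = np.meshgrid(gx, gy)
    if model.symmetry:
        pts = np.column_stack([np.abs(GY).ravel(), np.abs(GX).ravel()])
    else:
        pts = np.column_stack([GY.ravel(), GX.ravel()])
    w = interp(pts).reshape(grid_n, grid_n)
    return DeformationField(x=gx, y=gy, w=w)


def quantify_deformation(field: DeformationField, eps: float | None = None) -> FeatureTriple:
    """Reduce a deformation field to (max, total, thresholded area) features."""
    eps = 1e-6 if eps is None else eps
    w = field.w
    if w.size == 0:
        raise ValueError("empty deformation grid")
    f1 = float(w.max())
    f2 = float(w.sum())
    f3 = float(np.count_nonzero(w > eps) * field.cell_area)
    return FeatureTriple(f1=f1, f2=f2, f3=f3, unit_system="FEM")


_REFERENCE_CACHE: dict[tuple, np.ndarray] = {}


def reference_field(scenario: InclusionScenario, config: FemConfig | None = None) -> DeformationField:
    """Homogeneous-slab baseline field on the same mesh as ``scenario``.

    The baseline (uniform probe compression plus the punch-edge pressure ring)
    carries no inclusion information and, in the optical sensor, uniform
    contact produces no scattered light; the forward features are therefore
    measured on the *excess* field over this reference.  Cached per
    (config, fixed geometry) because the mesh is scenario-independent.
    """
    cfg = config or FemConfig()
    homog = dataclasses.replace(scenario, E_inc=scenario.E_bg)
    key = (cfg, homog.E_bg, homog.nu, homog.tissue_side, homog.tissue_thickness, homog.probe_side)
    if key not in _REFERENCE_CACHE:
        model = build_model(homog, cfg)
        _REFERENCE_CACHE[key] = solve_indentation(model)
    return _REFERENCE_CACHE[key]


def forward_field(scenario: InclusionScenario, config: FemConfig | None = None) -> DeformationField:
    """Inclusion-induced excess deformation of the probe bottom (mm).

    The homogeneous baseline is subtracted and values below the optical
    detectability floor are zeroed: what remains is the deformation pattern
    the tactile sensor can actually observe.
    """
    cfg = config or FemConfig()
    model = build_model(scenario, cfg)
    raw = solve_indentation(model)
    ref = reference_field(scenario, cfg)
    w = raw.w - ref.w
    w = np.where(w > cfg.detect_floor_mm, w, 0.0)
    return DeformationField(x=raw.x, y=raw.y, w=w)


def forward(scenario: InclusionScenario, config: FemConfig | None = None) -> FeatureTriple:
    """Full forward map: scenario -> mesh -> solve -> excess field -> features."""
    cfg = config or FemConfig()
    field = forward_field(scenario, cfg)
    return quantify_deformation(field, cfg.area_eps_mm)


def forward_features(
    scenarios: Iterable[InclusionScenario],
    config: FemConfig | None = None,
    progress: bool = False,
) -> list[FeatureTriple]:
    out = []
    scenarios = list(scenarios)
    for i, s in enumerate(scenarios):
        out.append(forward(s, config))
        if progress:
            print(f"  forward {i + 1}/{len(scenarios)}", flush=True)
    return out


# ---------------------------------------------------------------------------
# verification helper


def uniaxial_slab_model(
    E: float = 5.0,
    nu: float = 0.49,
    side: float = 20.0,
    thickness: float = 20.0,
    n: tuple[int, int, int] = (2, 2, 2),
) -> FemModel:
    """Confined-compression slab with no probe, for closed-form verification.

    Sides are constrained in their normal direction, the base is frictionless
    (u_z = 0 only) and the whole top surface is displaced downward by the
    prescribed indentation, producing an exact uniform uniaxial strain state:
    u = (0, 0, -indent * z / thickness).
    """
    nx, ny, nz = n
    xl = np.linspace(-side / 2, side / 2, nx + 1)
    yl = np.linspace(-side / 2, side / 2, ny + 1)
    zl = np.linspace(0.0, thickness, nz + 1)
    nodes = _grid_nodes(xl, yl, zl)
    elements = _grid_elements(nx, ny, nz)
    dims = _elem_dims(xl, yl, zl)
    m = len(elements)

    Ny, Nz = len(yl), len(zl)

    def nid(i, j, k):
        return (i * Ny + j) * Nz + k

    base = np.array([nid(i, j, 0) for i in range(nx + 1) for j in range(ny + 1)])
    top = np.array([nid(i, j, nz) for i in range(nx + 1) for j in range(ny + 1)])
    sx = np.flatnonzero(np.isclose(np.abs(nodes[:, 0]), side / 2))
    sy = np.flatnonzero(np.isclose(np.abs(nodes[:, 1]), side / 2))
    bcs = [
        (3 * base + 2, 0.0),
        (3 * top + 2, -1.0),
        (3 * sx, 0.0),
        (3 * sy + 1, 0.0),
    ]
    pb = np.array([[nid(i, j, nz) for i in range(nx + 1)] for j in range(ny + 1)])
    return FemModel(
        nodes=nodes,
        elements=elements,
        E=np.full(m, E),
        nu=np.full(m, nu),
        region=np.zeros(m, dtype=np.int8),
        dims=dims,
        ties=np.empty((0, 2), dtype=np.int64),
        bcs=bcs,
        pb_nodes=pb,
        pb_x=xl.copy(),
        pb_y=yl.copy(),
        symmetry=False,
        scenario=None,
        config=None,
    )


# ---------------------------------------------------------------------------
# plain-text mesh exchange


def write_mesh(model: FemModel, path) -> None:
    """Serialize a model (geometry, materials, constraints) to a text file."""
    with open(path, "w") as f:
        f.write("palpinv-mesh 1\n")
        f.write(f"SYMMETRY {int(model.symmetry)}\n")
        f.write(f"NODES {len(model.nodes)}\n")
        for x, y, z in model.nodes:
            f.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        f.write(f"ELEMENTS {len(model.elements)}\n")
        for row in model.elements:
            f.write(" ".join(str(v) for v in row) + "\n")
        f.write(f"MATERIALS {len(model.E)}\n")
        for e, nu, rg in zip(model.E, model.nu, model.region):
            f.write(f"{float(e)!r} {float(nu)!r} {int(rg)}\n")
        f.write(f"TIES {len(model.ties)}\n")
        for s, mast in model.ties:
            f.write(f"{s} {mast}\n")
        f.write(f"BCS {len(model.bcs)}\n")
        for dofs, scale in model.bcs:
            f.write(f"{float(scale)!r} " + " ".join(str(int(d)) for d in np.asarray(dofs).ravel()) + "\n")
        f.write(f"PB {model.pb_nodes.shape[0]} {model.pb_nodes.shape[1]}\n")
        f.write(" ".join(str(int(v)) for v in model.pb_nodes.ravel()) + "\n")
        f.write(" ".join(repr(float(v)) for v in model.pb_x) + "\n")
        f.write(" ".join(repr(float(v)) for v in model.pb_y) + "\n")


def read_mesh(path) -> FemModel:
    with open(path) as f:
        tokens = f.readline().split()
        if tokens[:1] != ["palpinv-mesh"]:
            raise ValueError("not a palpinv mesh file")
        symmetry = bool(int(f.readline().split()[1]))
        n = int(f.readline().split()[1])
        nodes = np.array([[float(v) for v in f.readline().split()] for _ in range(n)])
        m = int(f.readline().split()[1])
        elements = np.array([[int(v) for v in f.readline().split()] for _ in range(m)])
        k = int(f.readline().split()[1])
        mats = [f.readline().split() for _ in range(k)]
        E = np.array([float(r[0]) for r in mats])
        nu = np.array([float(r[1]) for r in mats])
        region = np.array([int(r[2]) for r in mats], dtype=np.int8)
        t = int(f.readline().split()[1])
        ties = np.array(
            [[int(v) for v in f.readline().split()] for _ in range(t)], dtype=np.int64
        ).reshape(t, 2)
        b = int(f.readline().split()[1])
        bcs = []
        for _ in range(b):
            parts = f.readline().split()
            bcs.append((np.array([int(v) for v in parts[1:]], dtype=np.int64), float(parts[0])))
        ny, nx = (int(v) for v in f.readline().split()[1:3])
        pb = np.array([int(v) for v in f.readline().split()], dtype=np.int64).reshape(ny, nx)
        pb_x = np.array([float(v) for v in f.readline().split()])
        pb_y = np.array([float(v) for v in f.readline().split()])
    dims = np.stack(
        [
            nodes[elements[:, 1], 0] - nodes[elements[:, 0], 0],
            nodes[elements[:, 3], 1] - nodes[elements[:, 0], 1],
            nodes[elements[:, 4], 2] - nodes[elements[:, 0], 2],
        ],
        axis=1,
    )
    model = FemModel(
        nodes=nodes,
        elements=elements,
        E=E,
        nu=nu,
        region=region,
        dims=dims,
        ties=ties,
        bcs=bcs,
        pb_nodes=pb,
        pb_x=pb_x,
        pb_y=pb_y,
        symmetry=symmetry,
    )
    model.validate()
    return model
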