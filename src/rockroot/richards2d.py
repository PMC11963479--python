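"""2D finite-volume Richards-equation solver for a single-root
rock-soil-root microdomain.

The governing equation is the mixed form of the Richards equation
without gravity (negligible over a millimetre-scale domain),

    rho_w * d(theta(psi))/dt = div( k(psi) grad psi ),

with psi in MPa, k in kg m-1 s-1 MPa-1 and theta volumetric.  Space is
discretized with cell-centered finite volumes on a structured grid
(4-neighbour fluxes, harmonic-mean inter-cell conductivity, which is
conservative across the sharp soil/rock contrast); time with backward
Euler and modified-Picard iteration (the mass-conservative mixed-form
linearisation), adaptive step halving on iteration failure.

Boundary conditions follow the modelled experiment: zero flux on the
rectangle sides (Neumann), fixed water potential on the root endodermis
ring (Dirichlet).  The module also provides geometry construction for
root-rock contact / no-contact scenarios, threshold-crossing timing of
result series, and Roache's Grid Convergence Index for solution
verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .constitutive import RHO_WATER, VGMBimodalParams, as_material
from .errors import DegenerateConvergenceError, GeometryError, ParameterError, SolverError

__all__ = [
    "SOIL",
    "ROCK",
    "ROOT",
    "MATERIAL_CODES",
    "DomainGeometry",
    "SimResult",
    "GCIReport",
    "build_domain",
    "simulate",
    "time_to_threshold",
    "gci",
]

SOIL, ROCK, ROOT = 0, 1, 2
MATERIAL_CODES = {"soil": SOIL, "rock": ROCK, "root": ROOT}
MATERIAL_NAMES = {v: k for k, v in MATERIAL_CODES.items()}

#: lattice pitch (mm) on which rock blocks are laid out, a common
#: multiple of the 50/100/200 um grids so refinement studies see
#: identical geometry
_BLOCK_LATTICE_MM = 0.2


@dataclass(frozen=True)
class DomainGeometry:
    """Structured-grid material map of the rock-soil-root rectangle.

    ``material_map`` is an (ny, nx) integer array of SOIL/ROCK/ROOT
    codes; ``endodermis_mask`` marks root cells on the root perimeter
    (the Dirichlet ring).  Cells are squares of side ``dx`` (= ``dy``),
    cell-centered, origin at the lower-left corner, row-major.
    """

    nx: int
    ny: int
    dx: float  # m
    dy: float  # m
    material_map: np.ndarray
    contact: bool
    rock_fraction_target: float
    root_diameter: float  # m
    endodermis_mask: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def area_m2(self) -> float:
        return self.nx * self.dx * self.ny * self.dy

    @property
    def rock_fraction(self) -> float:
        return float((self.material_map == ROCK).mean())

    @property
    def endodermis_cells(self) -> np.ndarray:
        """Flat (row-major) indices of the Dirichlet ring cells."""
        return np.flatnonzero(self.endodermis_mask.ravel())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates (m) of cell centers, each shaped (ny, nx)."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dy
        return np.meshgrid(x, y)


def _root_mask(nx: int, ny: int, dx: float, cx: float, cy: float, r: float) -> np.ndarray:
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    xx, yy = np.meshgrid(x, y)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _adjacency_count(a: np.ndarray, b: np.ndarray) -> int:
    """Number of 4-adjacent cell pairs with one cell in a, the other in b."""
    count = 0
    for axis in (0, 1):
        a0 = np.moveaxis(a, axis, 0)
        b0 = np.moveaxis(b, axis, 0)
        count += int((a0[:-1] & b0[1:]).sum()) + int((a0[1:] & b0[:-1]).sum())
    return count


def build_domain(
    area_mm2: float = 9.0,
    root_diameter_mm: float = 1.0,
    rock_fraction: float = 0.4,
    contact: bool = True,
    cell_um: float = 100.0,
    n_rock_blocks: int = 2,
    seed: int = 0,
) -> DomainGeometry:
    """Construct the square single-root domain with rock inclusions.

    The root is a centered disk (cells whose centers fall inside it);
    rock is laid out as rectangular blocks flanking the root, one side
    filled per block in alternation, on a 0.2 mm lattice so that the
    realized rock fraction is resolution-independent.  In contact mode
    the first block abuts the root disk; in no-contact mode every block
    keeps at least one lattice unit (>= 1 soil cell) away from the root.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= rock_fraction <= 0.8:
        raise GeometryError("rock_fraction must lie in [0, 0.8]")
    side_mm = math.sqrt(area_mm2)
    n_cells = side_mm * 1000.0 / cell_um
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise GeometryError(
            f"cell size {cell_um} um does not tile the {side_mm} mm domain side"
        )
    nx = ny = int(round(n_cells))
    dx = cell_um * 1e-6
    r_mm = root_diameter_mm / 2.0
    if root_diameter_mm + 2.0 * cell_um / 1000.0 > side_mm:
        raise GeometryError("root disk does not fit inside the rectangle")

    cx_mm = cy_mm = side_mm / 2.0
    rng = np.random.default_rng(seed)

    lat = _BLOCK_LATTICE_MM
    lat_cols = int(round(side_mm / lat))
    cell_per_lat = lat / (cell_um / 1000.0)
    if abs(cell_per_lat - round(cell_per_lat)) > 1e-9:
        raise GeometryError(
            f"cell size {cell_um} um must divide the {lat} mm block lattice"
        )

    # rock columns grow outward from the root disk on both sides: one
    # seeded "near" block abuts the disk, the others keep a one-column
    # soil gap.  The no-contact scenario uses the *same* layout with the
    # rock cells 4-adjacent to the root carved back to soil (a thin soil
    # film between root and rock), so the two scenarios differ only at
    # the root-rock interface.
    disk_left = cx_mm - r_mm
    disk_right = cx_mm + r_mm
    region_w = {"left": disk_left, "right": side_mm - disk_right}
    region_cols = {s: int(math.floor(w / lat + 1e-9)) for s, w in region_w.items()}

    lat_area = lat * lat
    target_cells = int(round(rock_fraction * area_mm2 / lat_area))
    start_col = {s: 1 for s in ("left", "right")}  # gap column by default
    capacity = (
        sum(region_cols.values()) - 1  # the near block's side has no gap
    ) * lat_cols
    if target_cells > capacity:
        raise GeometryError(
            f"rock fraction {rock_fraction:.2f} infeasible: needs {target_cells} "
            f"lattice cells, only {capacity} available"
        )

    # split the lattice-cell budget across blocks with seeded jitter
    blocks: list[tuple[float, float, float, float]] = []  # (x0, x1, y0, y1) mm
    if target_cells > 0:
        n_blocks = max(1, int(n_rock_blocks))
        shares = np.full(n_blocks, target_cells / n_blocks)
        if n_blocks > 1:
            jitter = rng.uniform(-0.1, 0.1, size=n_blocks)
            jitter -= jitter.mean()
            shares = shares * (1.0 + jitter)
        counts = np.floor(shares).astype(int)
        counts[-1] = target_cells - int(counts[:-1].sum())
        contact_side = str(rng.choice(["left", "right"]))
        sides = ["left", "right"]
        if contact_side == "right":
            sides = ["right", "left"]
        start_col[contact_side] = 0
        next_col = dict(start_col)

        def column_x(side: str, c: int) -> tuple[float, float]:
            # column c counts outward from the disk edge
            if side == "left":
                x0 = disk_left - (c + 1) * lat
            else:
                x0 = disk_right + c * lat
            return x0, x0 + lat

        for bi, count in enumerate(counts):
            count = int(count)
            side = sides[bi % 2]
            full_cols, part = divmod(count, lat_cols)
            ncols = full_cols + (1 if part else 0)
            if next_col[side] + ncols > region_cols[side]:
                side = sides[(bi + 1) % 2]
                if next_col[side] + ncols > region_cols[side]:
                    raise GeometryError("rock blocks do not fit in the side regions")
            c0 = next_col[side]
            for c in range(c0, c0 + full_cols):
                x0, x1 = column_x(side, c)
                blocks.append((x0, x1, 0.0, side_mm))
            if part:
                x0, x1 = column_x(side, c0 + full_cols)
                y0 = float(rng.integers(0, lat_cols - part + 1)) * lat
                blocks.append((x0, x1, y0, y0 + part * lat))
            next_col[side] = c0 + ncols

    # rasterize
    material = np.full((ny, nx), SOIL, dtype=np.int8)
    xx, yy = np.meshgrid(
        (np.arange(nx) + 0.5) * cell_um / 1000.0,
        (np.arange(ny) + 0.5) * cell_um / 1000.0,
    )
    for x0, x1, y0, y1 in blocks:
        inside = (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
        material[inside] = ROCK
    root = _root_mask(nx, ny, dx, cx_mm * 1e-3, cy_mm * 1e-3, r_mm * 1e-3)
    material[root] = ROOT
    if not contact:
        # carve the root-rock interface film back to soil
        film = (material == ROCK) & _shift_or(root, np.ones_like(root, dtype=bool))
        material[film] = SOIL

    # endodermis: root cells with a 4-neighbour outside the root
    non_root = material != ROOT
    ring = root & (
        _shift_or(non_root, root)
    )
    geom = DomainGeometry(
        nx=nx,
        ny=ny,
        dx=dx,
        dy=dx,
        material_map=material,
        contact=contact,
        rock_fraction_target=rock_fraction,
        root_diameter=root_diameter_mm * 1e-3,
        endodermis_mask=ring,
        seed=seed,
    )
    _validate_domain(geom)
    return geom


def _shift_or(mask: np.ndarray, within: np.ndarray) -> np.ndarray:
    """Cells of `within` having a 4-neighbour in `mask` (edges count as
    outside-root but not as neighbours)."""
    out = np.zeros_like(mask)
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out & within


def _validate_domain(g: DomainGeometry) -> None:
    rock = g.material_map == ROCK
    root = g.material_map == ROOT
    frac = g.rock_fraction
    if abs(frac - g.rock_fraction_target) > 0.02:
        raise GeometryError(
            f"realized rock fraction {frac:.3f} deviates more than 2 points "
            f"from target {g.rock_fraction_target:.3f}"
        )
    if root.any():
        _, n_comp = ndimage.label(root)  # 4-connectivity default
        if n_comp != 1:
            raise GeometryError("root cells are not a single 4-connected region")
        if not g.endodermis_mask.any():
            raise GeometryError("root has no perimeter (degenerate disk)")
    adj = _adjacency_count(rock, g.endodermis_mask)
    if g.contact and rock.any() and adj < 1:
        raise GeometryError("contact mode but no rock cell touches the root ring")
    if not g.contact and adj > 0:
        raise GeometryError("no-contact mode but rock touches the root ring")
    if not g.contact and rock.any():
        # at least one soil cell must separate root from rock everywhere
        near_root = _shift_or(root, np.ones_like(root, dtype=bool))
        if (rock & near_root).any():
            raise GeometryError("rock within one cell of the root in no-contact mode")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Time series and snapshots of one Richards run.

    ``psi_max_soil_rock`` is the maximum water potential over soil and
    rock cells (root cells excluded) at each saved time; water-content
    means are volumetric, per material and over soil+rock together
    (``theta_mean_total``).  ``mass_balance_residual`` is the cumulative
    storage-vs-boundary-flux mismatch relative to the initial stored
    mass.
    """

    times: np.ndarray
    psi_max_soil_rock: np.ndarray
    theta_mean_total: np.ndarray
    theta_mean_by_material: dict[str, np.ndarray]
    mass_balance_residual: float
    snapshots: list[tuple[float, np.ndarray, np.ndarray]]  # (t, psi, theta)
    domain: DomainGeometry
    picard_iterations_total: int = 0
    cumulative_root_uptake: float = 0.0  # kg per m of domain thickness

    @property
    def theta_mean_soil(self) -> np.ndarray:
        return self.theta_mean_by_material["soil"]

    @property
    def theta_mean_rock(self) -> np.ndarray:
        return self.theta_mean_by_material.get(
            "rock", np.full_like(self.times, np.nan)
        )

    def series(self, name: str) -> np.ndarray:
        known = {
            "psi_max": self.psi_max_soil_rock,
            "psi_max_soil_rock": self.psi_max_soil_rock,
            "theta_mean_total": self.theta_mean_total,
            "theta_mean_soil": self.theta_mean_soil,
            "theta_mean_rock": self.theta_mean_rock,
        }
        for mat, arr in self.theta_mean_by_material.items():
            known[f"theta_mean_{mat}"] = arr
        if name not in known:
            raise KeyError(
                f"unknown series {name!r}; available: {sorted(known)}"
            )
        return known[name]


def simulate(
    domain: DomainGeometry,
    params_by_material: dict,
    psi_init: float = 0.0,
    psi_root: float = -1.5,
    t_end: float = 3600.0,
    dt_init: float = 1e-2,
    dt_max: float = 10.0,
    dt_min: float = 1e-3,
    picard_tol: float = 1e-6,
    max_picard: int = 50,
    snapshot_every: float | None = None,
) -> SimResult:
    """Run the Richards simulation on a built domain.

    ``params_by_material`` maps material names present in the domain
    ('soil', 'rock', 'root') to either :class:`VGMBimodalParams` or
    material objects exposing ``water_content/capacity/conductivity``.
    A parameter set under 'root' is wrapped with constant conductivity
    (a single measured root conductivity spans the potential range).
    The endodermis ring is held at ``psi_root`` (Dirichlet); all outer
    boundaries are zero-flux.
    """
    if not psi_root <= psi_init <= 0.0:
        raise ParameterError("require psi_root <= psi_init <= 0")
    present = {MATERIAL_NAMES[c] for c in np.unique(domain.material_map)}
    missing = present - set(params_by_material)
    if missing:
        raise ParameterError(f"missing material parameters for: {sorted(missing)}")
    materials = {
        name: as_material(obj, constant_k=(name == "root"))
        for name, obj in params_by_material.items()
        if name in present
    }

    ny, nx = domain.ny, domain.nx
    N = nx * ny
    dx, dy = domain.dx, domain.dy
    cell_vol = dx * dy * 1.0  # unit thickness (m); masses are per m depth
    mat = domain.material_map.ravel()
    mat_masks = {name: mat == code for name, code in MATERIAL_CODES.items() if (mat == code).any()}
    dirichlet = domain.endodermis_mask.ravel()
    free = ~dirichlet

    def eval_fields(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # saturated extension: iterates may transiently exceed psi = 0,
        # where theta = theta_s, C = 0 and k = Ks
        psi = np.minimum(psi, 0.0)
        theta = np.empty(N)
        cap = np.empty(N)
        cond = np.empty(N)
        for name, mask in mat_masks.items():
            m = materials[name]
            p = psi[mask]
            theta[mask] = m.water_content(p)
            cap[mask] = m.capacity(p)
            cond[mask] = m.conductivity(p)
        return theta, cap, cond

    # face index lists (4-neighbour structured grid)
    idx = np.arange(N).reshape(ny, nx)
    fh_a = idx[:, :-1].ravel()  # horizontal faces: a-b left-right
    fh_b = idx[:, 1:].ravel()
    fv_a = idx[:-1, :].ravel()  # vertical faces: a-b bottom-top
    fv_b = idx[1:, :].ravel()
    face_a = np.concatenate([fh_a, fv_a])
    face_b = np.concatenate([fh_b, fv_b])
    # geometric transmissibility factor: area / distance (unit thickness)
    face_geo = np.concatenate(
        [np.full(fh_a.size, dy / dx), np.full(fv_a.size, dx / dy)]
    )

    def face_trans(cond: np.ndarray) -> np.ndarray:
        ka, kb = cond[face_a], cond[face_b]
        return face_geo * 2.0 * ka * kb / (ka + kb)

    psi = np.full(N, float(psi_init))
    psi[dirichlet] = psi_root
    theta_n, _, _ = eval_fields(psi)
    mass0 = float((theta_n[free] * cell_vol * RHO_WATER).sum())

    soilrock = free_sr = (mat != ROOT)
    times = [0.0]
    psi_max = [float(psi[soilrock].max()) if soilrock.any() else float(psi.max())]
    theta_by_mat: dict[str, list[float]] = {
        name: [float(theta_n[mask].mean())] for name, mask in mat_masks.items()
    }
    theta_total = [float(theta_n[soilrock].mean())] if soilrock.any() else [float(theta_n.mean())]
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []
    next_snap = snapshot_every if snapshot_every else np.inf

    t = 0.0
    dt = float(dt_init)
    cumulative_flux = 0.0  # kg per m thickness, positive = into root
    total_picard = 0
    rho_v = RHO_WATER * cell_vol

    rows_free = np.flatnonzero(free)

    while t < t_end - 1e-12:
        dt = min(dt, t_end - t)
        accepted = False
        while not accepted:
            psi_k = psi.copy()
            converged = False
            omega = 1.0  # under-relaxation, reduced when iterates oscillate
            upd_prev: np.ndarray | None = None
            for _ in range(max_picard):
                theta_k, cap_k, cond_k = eval_fields(psi_k)
                # chord-slope capacity where the iterate has moved: adds the
                # true storage inertia for cells leaving saturation (where
                # the analytic C vanishes); at convergence the capacity term
                # drops out, so this only steers the iteration
                psi_eff = np.minimum(psi_k, 0.0)
                moved = np.abs(psi_eff - psi) > 1e-9
                chord = np.zeros_like(cap_k)
                chord[moved] = (theta_k[moved] - theta_n[moved]) / (
                    psi_eff[moved] - psi[moved]
                )
                cap_k = np.where(moved & (chord > 0), chord, cap_k)
                T = face_trans(cond_k)
                # assemble: (rho V C/dt) psi + sum T (psi_i - psi_j) = rhs
                diag = np.zeros(N)
                np.add.at(diag, face_a, T)
                np.add.at(diag, face_b, T)
                diag += rho_v * cap_k / dt
                rhs = rho_v * (cap_k * psi_k - (theta_k - theta_n)) / dt
                # Dirichlet rows: identity
                diag_d = diag.copy()
                diag_d[dirichlet] = 1.0
                rhs[dirichlet] = psi_root
                keep = free[face_a] | free[face_b]  # drop D-D couplings only
                fa, fb, Tf = face_a[keep], face_b[keep], T[keep]
                # off-diagonals only for free rows
                row_off = np.concatenate([fa[free[fa]], fb[free[fb]]])
                col_off = np.concatenate([fb[free[fa]], fa[free[fb]]])
                val_off = np.concatenate([-Tf[free[fa]], -Tf[free[fb]]])
                rows = np.concatenate([np.arange(N), row_off])
                cols = np.concatenate([np.arange(N), col_off])
                vals = np.concatenate([diag_d, val_off])
                A = csr_matrix((vals, (rows, cols)), shape=(N, N))
                psi_new = splu(A.tocsc()).solve(rhs)
                # lower safeguard only: the solution cannot undershoot the
                # root boundary potential (maximum principle); overshoot
                # above 0 is handled by the saturated extension
                np.maximum(psi_new, psi_root, out=psi_new)
                total_picard += 1
                delta = float(np.abs(psi_new[free] - psi_k[free]).max()) if free.any() else 0.0
                if delta < picard_tol:
                    psi_k = psi_new
                    converged = True
                    break
                upd = psi_new - psi_k
                if upd_prev is not None and float(upd @ upd_prev) < 0.0:
                    # successive updates point in opposite directions:
                    # the fixed-point map is oscillating, damp it
                    omega = max(0.1, omega * 0.5)
                else:
                    omega = min(1.0, omega * 1.5)
                psi_k = psi_k + omega * upd
                upd_prev = upd
            if converged:
                accepted = True
            else:
                dt *= 0.5
                if dt < dt_min:
                    raise SolverError(
                        f"Picard iteration failed at t = {t:.3f} s with "
                        f"dt = {dt * 2:.2e} s (min {dt_min}); max residual "
                        f"{delta:.3e} MPa"
                    )

        # accept the step; fold any residual saturated overshoot back to
        # the admissible range
        np.clip(psi_k, psi_root, psi_init, out=psi_k)
        theta_new, _, cond_new = eval_fields(psi_k)
        T = face_trans(cond_new)
        # flux into Dirichlet cells across D-free faces (kg/s per m depth)
        df = dirichlet[face_a] & free[face_b]
        fd = free[face_a] & dirichlet[face_b]
        q_root = float((T[df] * (psi_k[face_b[df]] - psi_root)).sum()) + float(
            (T[fd] * (psi_k[face_a[fd]] - psi_root)).sum()
        )
        cumulative_flux += q_root * dt
        theta_n = theta_new
        psi = psi_k
        t += dt

        times.append(t)
        psi_max.append(float(psi[soilrock].max()) if soilrock.any() else float(psi.max()))
        for name, mask in mat_masks.items():
            theta_by_mat[name].append(float(theta_n[mask].mean()))
        theta_total.append(
            float(theta_n[soilrock].mean()) if soilrock.any() else float(theta_n.mean())
        )
        if t + 1e-9 >= next_snap:
            snapshots.append(
                (t, psi.reshape(ny, nx).copy(), theta_n.reshape(ny, nx).copy())
            )
            next_snap += snapshot_every

        dt = min(dt * 1.3, dt_max)

    mass_end = float((theta_n[free] * cell_vol * RHO_WATER).sum())
    residual = abs((mass0 - mass_end) - cumulative_flux) / mass0 if mass0 > 0 else 0.0

    result = SimResult(
        times=np.asarray(times),
        psi_max_soil_rock=np.asarray(psi_max),
        theta_mean_total=np.asarray(theta_total),
        theta_mean_by_material={k: np.asarray(v) for k, v in theta_by_mat.items()},
        mass_balance_residual=residual,
        snapshots=snapshots,
        domain=domain,
        picard_iterations_total=total_picard,
        cumulative_root_uptake=cumulative_flux,
    )
    return result


def time_to_threshold(
    result: SimResult,
    series: str,
    threshold: float | None = None,
    fraction_of_initial: float | None = None,
) -> float:
    """First time a saved series crosses a threshold (s), linearly
    interpolated between the bracketing saved times.

    Either an absolute ``threshold`` or ``fraction_of_initial`` (the
    threshold is that fraction of the series' initial value) must be
    given.  Returns ``inf`` if the series never crosses within the run.
    """
    y = result.series(series)
    t = result.times
    if fraction_of_initial is not None:
        threshold = fraction_of_initial * y[0]
    if threshold is None:
        raise ValueError("provide threshold or fraction_of_initial")
    descending = y[0] > threshold
    if descending:
        hit = y <= threshold
    else:
        hit = y >= threshold
    if not hit.any():
        return math.inf
    i = int(np.argmax(hit))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (threshold - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def series_crossings(
    a: SimResult,
    b: SimResult,
    series: str = "psi_max",
    band: float = 5e-4,
    n_grid: int = 4000,
) -> list[float]:
    """Times (s) at which a saved series of run ``a`` crosses that of ``b``.

    Both series are interpolated onto a common time grid; a crossing is
    counted with hysteresis: the difference must leave the ``+-band``
    dead zone on one side and re-emerge on the other.  ``band`` (MPa for
    potential series) suppresses spurious flips from time-step
    interpolation noise; set it to the numerical resolution of the
    saved series.
    """
    t_max = min(a.times[-1], b.times[-1])
    tg = np.linspace(0.0, t_max, n_grid)
    diff = np.interp(tg, a.times, a.series(series)) - np.interp(
        tg, b.times, b.series(series)
    )
    crossings: list[float] = []
    state = 0  # -1, 0, +1: last side of the dead zone the difference left
    for t, d in zip(tg, diff):
        side = 1 if d > band else (-1 if d < -band else 0)
        if side != 0:
            if state != 0 and side != state:
                crossings.append(float(t))
            state = side
    return crossings


# ---------------------------------------------------------------------------
# grid convergence index (Roache)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GCIReport:
    """Grid-convergence verification of a monitored scalar.

    ``p`` is the observed order of convergence; ``gci_fine`` and
    ``gci_medium`` are the standardized discretization-error estimates
    (%) on the fine and medium grids; an ``asymptotic_ratio`` near 1
    indicates the grids are in the asymptotic convergence range.
    """

    f_fine: float
    f_medium: float
    f_coarse: float
    r: float
    p: float
    gci_fine: float
    gci_medium: float
    asymptotic_ratio: float


def gci(
    f_coarse: float,
    f_medium: float,
    f_fine: float,
    r: float = 2.0,
    Fs: float = 1.25,
) -> GCIReport:
    """Roache's Grid Convergence Index from three grid levels.

    With f1 = fine, f2 = medium, f3 = coarse and refinement ratio r:

        p         = ln((f3 - f2) / (f2 - f1)) / ln r
        GCI_fine  = Fs |(f2 - f1) / f1| / (r^p - 1) * 100%
        GCI_med   = Fs |(f3 - f2) / f2| / (r^p - 1) * 100%
        ratio     = GCI_med / (r^p * GCI_fine)
    """
    if r <= 1:
        raise DegenerateConvergenceError("refinement ratio must be > 1")
    f1, f2, f3 = float(f_fine), float(f_medium), float(f_coarse)
    d21, d32 = f2 - f1, f3 - f2
    if d21 == 0.0 or d32 == 0.0:
        raise DegenerateConvergenceError(
            "identical solutions on successive grids: observed order undefined"
        )
    ratio = d32 / d21
    if ratio <= 0.0:
        raise DegenerateConvergenceError(
            f"oscillatory convergence (error ratio {ratio:.3g} <= 0)"
        )
    p = math.log(ratio) / math.log(r)
    if f1 == 0.0 or f2 == 0.0:
        raise DegenerateConvergenceError("zero reference solution in GCI")
    gci_fine = Fs * abs(d21 / f1) / (r**p - 1.0) * 100.0
    gci_medium = Fs * abs(d32 / f2) / (r**p - 1.0) * 100.0
    return GCIReport(
        f_fine=f1,
        f_medium=f2,
        f_coarse=f3,
        r=float(r),
        p=p,
        gci_fine=gci_fine,
        gci_medium=gci_medium,
        asymptotic_ratio=gci_medium / (r**p * gci_fine),
    )
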