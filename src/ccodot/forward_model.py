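"""Continuous-wave diffusion-approximation forward model on a regular grid.

The photon fluence Φ obeys

    −∇·(κ ∇Φ) + μa Φ = q,   κ = 1 / (3 (μa + μs′)),

with a Robin (partial-current) boundary condition by default,
Φ + 2Aκ ∂Φ/∂n = 0, where A encodes the internal-reflection mismatch for a
tissue refractive index of 1.4.  The equation is discretized with a
finite-volume 7-point stencil on a regular voxel grid (harmonic-mean face
diffusivities), yielding a symmetric positive-definite sparse system that is
shared between forward (source) and adjoint (detector) solves.

Channel sensitivities use the Rytov (log-attenuation) linearization:
J(ch, v) = Φ_src(v) Φ_det(v) V_v / (y_ch ln 10) is the derivative of the
channel's log10 attenuation with respect to the voxel absorption
coefficient (units OD per mm⁻¹).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg

__all__ = [
    "Grid",
    "Geometry",
    "OpticalProperties",
    "OptodeArray",
    "WavelengthJacobian",
    "layered_slab",
    "load_tissue_optics",
    "DiffusionSolver",
    "solve_diffusion",
    "compute_jacobian",
    "project_to_grid",
    "project_jacobian",
    "coarsen_grid",
    "boundary_profile",
    "reflection_parameter",
]

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: ``origin`` (mm), isotropic ``spacing`` (mm), shape."""

    shape: tuple
    spacing: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing ** 3)

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * self.spacing

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing

    def centers(self) -> np.ndarray:
        """Voxel-center coordinates, shape (n_voxels, 3), C-order flattening."""
        ax = [self.axis_centers(i) for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass
class Geometry:
    """Voxelized domain with per-voxel tissue labels.

    ``labels`` holds integer tissue codes; ``tissue_names`` maps code →
    tissue identifier used to look up optical properties.  The domain
    boundary is the surface of the bounding box (all six faces).
    """

    grid: Grid
    labels: np.ndarray
    tissue_names: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape must match grid shape")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.tissue_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no tissue name")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def spacing(self):
        return self.grid.spacing

    def tissue_map(self) -> np.ndarray:
        """Per-voxel tissue identifier array (object dtype)."""
        lut = np.empty(max(self.tissue_names) + 1, dtype=object)
        for code, name in self.tissue_names.items():
            lut[code] = name
        return lut[self.labels]

    def mask(self, tissue: str) -> np.ndarray:
        codes = [c for c, n in self.tissue_names.items() if n == tissue]
        return np.isin(self.labels, codes)

    def refine(self, factor: int = 2) -> "Geometry":
        """Same domain at ``factor``× finer spacing (labels replicated)."""
        lab = self.labels
        for ax in range(3):
            lab = np.repeat(lab, factor, axis=ax)
        g = Grid(tuple(s * factor for s in self.grid.shape),
                 self.grid.spacing / factor, self.grid.origin)
        return Geometry(g, lab, dict(self.tissue_names))


def layered_slab(extent_mm=(108.0, 63.0, 42.0), spacing=2.0,
                 scalp_skull_mm=12.0, csf_mm=2.0) -> Geometry:
    """Three-layer slab phantom: scalp+skull / CSF / brain along +z (depth).

    z = 0 is the outer (optode) surface.  Layer membership is decided by
    voxel-center depth, so layers thinner than the spacing occupy at least
    one voxel plane when their band contains a center.
    """
    shape = tuple(int(round(e / spacing)) for e in extent_mm)
    g = Grid(shape, spacing)
    z = g.axis_centers(2)
    layer = np.where(z < scalp_skull_mm, 1,
                     np.where(z < scalp_skull_mm + csf_mm, 2, 3))
    labels = np.broadcast_to(layer[None, None, :], shape).copy()
    return Geometry(g, labels, {1: "scalp_skull", 2: "csf", 3: "brain"})


def reflection_parameter(n: float = 1.4) -> float:
    """Internal-reflection parameter A for the partial-current boundary.

    Uses the Groenhuis polynomial fit for the effective reflection
    coefficient of a refractive-index mismatch n (tissue/air).
    """
    r_eff = -1.440 / n ** 2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass
class OpticalProperties:
    """Per-tissue, per-wavelength absorption and reduced scattering (mm⁻¹)."""

    table: dict  # tissue -> (wavelengths_nm, mua, musp)
    refractive_index: float = 1.4

    def _interp(self, tissue: str, wavelength: float, col: int) -> float:
        if tissue not in self.table:
            raise KeyError(f"no optical properties for tissue {tissue!r}")
        wl, mua, musp = self.table[tissue]
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(
                f"wavelength {wavelength:g} nm outside optical-property table "
                f"range [{wl[0]:g}, {wl[-1]:g}] for tissue {tissue!r}"
            )
        return float(np.interp(wavelength, wl, (mua, musp)[col]))

    def mua(self, tissue: str, wavelength: float) -> float:
        return self._interp(tissue, wavelength, 0)

    def musp(self, tissue: str, wavelength: float) -> float:
        return self._interp(tissue, wavelength, 1)

    def maps(self, geometry: Geometry, wavelength: float):
        """(mua, musp) per-voxel arrays at one wavelength."""
        mua = np.empty(geometry.shape)
        musp = np.empty(geometry.shape)
        for code, name in geometry.tissue_names.items():
            m = geometry.labels == code
            if m.any():
                mua[m] = self.mua(name, wavelength)
                musp[m] = self.musp(name, wavelength)
        if np.any(mua < 0) or np.any(musp <= 0):
            raise ValueError("require mua >= 0 and musp > 0 everywhere")
        return mua, musp

    @classmethod
    def homogeneous(cls, mua: float, musp: float, n: float = 1.4,
                    tissue: str = "medium") -> "OpticalProperties":
        wl = np.array([600.0, 1100.0])
        return cls({tissue: (wl, np.full(2, mua), np.full(2, musp))},
                   refractive_index=n)


def load_tissue_optics(path=None, refractive_index: float = 1.4) -> OpticalProperties:
    """Load the per-tissue optical-property table (packaged default)."""
    if path is None:
        text = (resources.files("ccodot") / "data"
                / "tissue_optics_synthetic.csv").read_text()
    else:
        text = open(path).read()
    df = pd.read_csv(io.StringIO(text), comment="#")
    table = {}
    for tissue, sub in df.groupby("tissue"):
        sub = sub.sort_values("wavelength_nm")
        table[tissue] = (sub["wavelength_nm"].to_numpy(float),
                         sub["mua_per_mm"].to_numpy(float),
                         sub["musp_per_mm"].to_numpy(float))
    return OpticalProperties(table, refractive_index=refractive_index)


@dataclass
class OptodeArray:
    """Source/detector positions (mm) and the channel pairing.

    ``channels`` lists (source_index, detector_index) pairs; each defines
    one measurement.  Boundary sources and detectors are modelled as
    Gaussian profiles of standard deviation ``source_sigma`` mm on the
    nearest domain face, truncated at 3σ and renormalized to unit power.
    """

    sources: np.ndarray
    detectors: np.ndarray
    channels: list
    source_sigma: float = 2.0

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.detectors = np.atleast_2d(np.asarray(self.detectors, dtype=float))
        for si, di in self.channels:
            if not (0 <= si < len(self.sources) and 0 <= di < len(self.detectors)):
                raise ValueError(f"channel ({si}, {di}) references missing optode")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_distances(self) -> np.ndarray:
        """Euclidean source–detector distance per channel (mm)."""
        return np.array([
            np.linalg.norm(self.sources[si] - self.detectors[di])
            for si, di in self.channels
        ])

    def to_csv(self, path) -> None:
        rows = [("S%d" % i, "source", *p) for i, p in enumerate(self.sources)]
        rows += [("D%d" % i, "detector", *p) for i, p in enumerate(self.detectors)]
        pd.DataFrame(rows, columns=["id", "type", "x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, optode_path, channel_path, source_sigma: float = 2.0):
        df = pd.read_csv(optode_path)
        src = df[df["type"] == "source"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        det = df[df["type"] == "detector"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        ch = pd.read_csv(channel_path)
        channels = list(zip(ch["source_id"].astype(int), ch["detector_id"].astype(int)))
        return cls(src, det, channels, source_sigma=source_sigma)

    def channels_to_csv(self, path) -> None:
        pd.DataFrame(self.channels, columns=["source_id", "detector_id"]).to_csv(
            path, index=False)


@dataclass
class WavelengthJacobian:
    """Channel × voxel sensitivity of log10 attenuation to Δμa at one λ."""

    wavelength_nm: float
    matrix: np.ndarray  # (n_channels, n_voxels)
    grid: Grid
    baseline: np.ndarray | None = None  # modeled channel amplitude y_ch

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.grid.n_voxels:
            raise ValueError("Jacobian shape must be (n_channels, n_voxels)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian entries must be finite")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def boundary_profile(geometry: Geometry, position, sigma: float = 2.0) -> np.ndarray:
    """Unit-power optode profile on the nearest domain face.

    The position is snapped to the closest face of the bounding box; a
    Gaussian of standard deviation ``sigma`` mm (truncated at 3σ) weights
    the voxels of that face, normalized to unit total power.  ``sigma = 0``
    gives a single-voxel (delta) profile.
    """
    g = geometry.grid
    pos = np.asarray(position, dtype=float)
    lo = np.asarray(g.origin)
    hi = lo + g.extent
    # nearest face: the axis/side minimizing distance to the box surface
    d_lo, d_hi = np.abs(pos - lo), np.abs(pos - hi)
    ax = int(np.argmin(np.minimum(d_lo, d_hi)))
    side = 0 if d_lo[ax] <= d_hi[ax] else -1
    q = np.zeros(g.shape)
    inplane = [a for a in range(3) if a != ax]
    c0 = g.axis_centers(inplane[0])
    c1 = g.axis_centers(inplane[1])
    D0, D1 = np.meshgrid(c0 - pos[inplane[0]], c1 - pos[inplane[1]], indexing="ij")
    r2 = D0 ** 2 + D1 ** 2
    if sigma > 0:
        w = np.where(r2 <= (3.0 * sigma) ** 2, np.exp(-r2 / (2.0 * sigma ** 2)), 0.0)
    else:
        w = np.zeros_like(r2)
        w[np.unravel_index(np.argmin(r2), r2.shape)] = 1.0
    if w.sum() <= 0:
        raise ValueError("optode profile does not intersect the domain boundary")
    w = w / w.sum()
    sl = [slice(None)] * 3
    sl[ax] = side
    q[tuple(sl)] = w
    return q


class DiffusionSolver:
    """Factorized finite-volume diffusion operator at one wavelength.

    Builds the SPD system for a geometry/optical-property pair and exposes
    repeated solves against many right-hand sides (sources and adjoint
    detector profiles).  Systems up to ~1.5e5 unknowns use a sparse LU
    factorization; larger ones fall back to Jacobi-preconditioned CG.
    """

    def __init__(self, geometry: Geometry, props: OpticalProperties,
                 wavelength: float, boundary: str = "robin",
                 mua: np.ndarray | None = None, musp: np.ndarray | None = None):
        if boundary not in ("robin", "neumann"):
            raise ValueError("boundary must be 'robin' or 'neumann'")
        self.geometry = geometry
        self.wavelength = float(wavelength)
        self.boundary = boundary
        # explicit voxel-wise fields override the tissue table (used e.g.
        # for perturbation studies around a tissue-based baseline)
        mua_t, musp_t = props.maps(geometry, wavelength)
        mua = mua_t if mua is None else np.asarray(mua, dtype=float)
        musp = musp_t if musp is None else np.asarray(musp, dtype=float)
        if mua.shape != geometry.shape or musp.shape != geometry.shape:
            raise ValueError("override fields must match the grid shape")
        if np.any(mua < 0) or np.any(musp <= 0):
            raise ValueError("require mua >= 0 and musp > 0 everywhere")
        self.mua, self.musp = mua, musp
        h = geometry.spacing
        kappa = 1.0 / (3.0 * (mua + musp))
        n = geometry.grid.n_voxels
        shape = geometry.shape
        idx = np.arange(n).reshape(shape)
        diag = mua.ravel() * h ** 3
        rows, cols, vals = [], [], []
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(None, -1)
            sl_b[ax] = slice(1, None)
            ka = kappa[tuple(sl_a)]
            kb = kappa[tuple(sl_b)]
            cond = (2.0 * ka * kb / (ka + kb)) * h  # harmonic mean × area / h
            ia = idx[tuple(sl_a)].ravel()
            ib = idx[tuple(sl_b)].ravel()
            c = cond.ravel()
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [-c, -c]
            np.add.at(diag, ia, c)
            np.add.at(diag, ib, c)
        if boundary == "robin":
            A = reflection_parameter(props.refractive_index)
            for ax in range(3):
                for side in (0, -1):
                    sl = [slice(None)] * 3
                    sl[ax] = side
                    face_idx = idx[tuple(sl)].ravel()
                    kf = kappa[tuple(sl)].ravel()
                    coeff = h ** 2 / (2.0 * A + h / (2.0 * kf))
                    np.add.at(diag, face_idx, coeff)
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        K = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)).tocsc()
        self.matrix = K
        self._n = n
        if boundary == "neumann" and np.all(mua == 0):
            raise np.linalg.LinAlgError(
                "singular system: zero absorption with pure Neumann boundary")
        self._minv = sparse.diags(1.0 / K.diagonal())

    def solve(self, q, rtol: float = 1e-12) -> np.ndarray:
        """Fluence field for source power density ``q`` (per-voxel power).

        Solved with Jacobi-preconditioned conjugate gradients on the SPD
        system; the tight default tolerance makes repeated solves agree to
        well below the discretization error.
        """
        b = np.asarray(q, dtype=float).ravel()
        if b.size != self._n:
            raise ValueError("source vector size mismatch")
        phi, info = cg(self.matrix, b, M=self._minv, rtol=rtol, atol=0.0,
                       maxiter=20_000)
        if info != 0:
            raise np.linalg.LinAlgError(f"CG failed to converge (info={info})")
        return phi.reshape(self.geometry.shape)


def solve_diffusion(geometry, props, wavelength, source,
                    boundary: str = "robin") -> np.ndarray:
    """Fluence for one source (a boundary position or an explicit field)."""
    solver = DiffusionSolver(geometry, props, wavelength, boundary=boundary)
    if isinstance(source, (tuple, list, np.ndarray)) and np.asarray(source).size == 3 \
            and np.asarray(source).ndim == 1:
        q = boundary_profile(geometry, source, sigma=0.0)
    else:
        q = np.asarray(source, dtype=float)
        if q.shape != geometry.shape:
            q = q.reshape(geometry.shape)
    return solver.solve(q)


def compute_jacobian(geometry: Geometry, props: OpticalProperties,
                     array: OptodeArray, wavelength: float,
                     boundary: str = "robin",
                     solver: DiffusionSolver | None = None) -> WavelengthJacobian:
    """Adjoint (Rytov) sensitivity matrix for every channel at one wavelength.

    For channel (s, d): J(v) = Φ_s(v) Φ_d(v) V_v / (y ln 10) with
    y = ⟨q_d, Φ_s⟩ the modeled channel amplitude.  Reciprocity (source ↔
    detector exchange) holds exactly because the discrete operator is
    symmetric.
    """
    if solver is None:
        solver = DiffusionSolver(geometry, props, wavelength, boundary=boundary)
    src_idx = sorted({si for si, _ in array.channels})
    det_idx = sorted({di for _, di in array.channels})
    q_src = {i: boundary_profile(geometry, array.sources[i], array.source_sigma)
             for i in src_idx}
    q_det = {i: boundary_profile(geometry, array.detectors[i], array.source_sigma)
             for i in det_idx}
    phi_src = {i: solver.solve(q_src[i]) for i in src_idx}
    phi_det = {i: solver.solve(q_det[i]) for i in det_idx}
    V = geometry.grid.voxel_volume
    n_vox = geometry.grid.n_voxels
    J = np.empty((array.n_channels, n_vox))
    y = np.empty(array.n_channels)
    for k, (si, di) in enumerate(array.channels):
        yk = float(np.vdot(q_det[di].ravel(), phi_src[si].ravel()))
        if not np.isfinite(yk) or yk <= 0:
            raise ValueError(
                f"degenerate channel {k} (source {si}, detector {di}): "
                f"modeled signal {yk:g}"
            )
        J[k] = phi_src[si].ravel() * phi_det[di].ravel() * (V / (yk * LN10))
        y[k] = yk
    return WavelengthJacobian(wavelength, J, geometry.grid, baseline=y)


# ---------------------------------------------------------------------------
# grid projection

def coarsen_grid(grid: Grid, spacing: float) -> Grid:
    """Covering grid with the same origin at a coarser spacing.

    The shape is rounded up so the coarse grid always covers the source
    domain (it may extend up to one voxel beyond it).
    """
    shape = tuple(int(np.ceil(e / spacing - 1e-9)) for e in grid.extent)
    return Grid(shape, spacing, grid.origin)


def _overlap_matrix(src_edges: np.ndarray, dst_edges: np.ndarray) -> sparse.csr_matrix:
    """Sparse (n_dst × n_src) matrix of interval-overlap lengths."""
    rows, cols, vals = [], [], []
    j0 = 0
    for i in range(len(dst_edges) - 1):
        a, b = dst_edges[i], dst_edges[i + 1]
        for j in range(len(src_edges) - 1):
            lo = max(a, src_edges[j])
            hi = min(b, src_edges[j + 1])
            if hi > lo + 1e-12:
                rows.append(i)
                cols.append(j)
                vals.append(hi - lo)
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(len(dst_edges) - 1, len(src_edges) - 1))


def _axis_edges(grid: Grid, axis: int) -> np.ndarray:
    return grid.origin[axis] + np.arange(grid.shape[axis] + 1) * grid.spacing


def project_to_grid(field: np.ndarray, src_grid: Grid, dst_grid: Grid,
                    conserve: str = "mean") -> np.ndarray:
    """Mass-preserving resampling between regular grids (exact overlaps).

    ``conserve="mean"`` returns the volume-weighted mean over each target
    voxel (for intensive fields such as μa or concentration: the integral
    ∫ field dV over the common support is preserved).  ``conserve="integral"``
    returns the integrated mass per target voxel (for per-voxel extensive
    quantities already carrying a volume factor, divided by the source
    voxel volume internally).
    """
    field = np.asarray(field, dtype=float).reshape(src_grid.shape)
    lo_s = np.asarray(src_grid.origin)
    lo_d = np.asarray(dst_grid.origin)
    if np.any(lo_d > lo_s + 1e-9) or np.any(
            lo_d + dst_grid.extent < lo_s + src_grid.extent - 1e-9):
        raise ValueError("target grid does not cover the source domain")
    W = [_overlap_matrix(_axis_edges(src_grid, ax), _axis_edges(dst_grid, ax))
         for ax in range(3)]
    out = field
    for ax in range(3):
        out = np.moveaxis(np.tensordot(W[ax].toarray(), np.moveaxis(out, ax, 0),
                                       axes=(1, 0)), 0, ax)
    if conserve == "integral":
        return out / src_grid.voxel_volume
    vol = np.ones(src_grid.shape)
    for ax in range(3):
        vol = np.moveaxis(np.tensordot(W[ax].toarray(), np.moveaxis(vol, ax, 0),
                                       axes=(1, 0)), 0, ax)
    covered = vol > 0
    res = np.zeros(dst_grid.shape)
    res[covered] = out[covered] / vol[covered]
    return res


def project_jacobian(jac: WavelengthJacobian, dst_grid: Grid) -> WavelengthJacobian:
    """Aggregate Jacobian columns onto a coarser reconstruction grid.

    Entries carry the voxel volume, so the projection sums the fine-voxel
    sensitivities overlapping each target voxel: J_dst · Δμa equals
    J_src · Δμa for any absorption field constant on target voxels.
    """
    rows = [
        project_to_grid(row, jac.grid, dst_grid, conserve="integral").ravel()
        for row in jac.matrix
    ]
    return WavelengthJacobian(jac.wavelength_nm, np.vstack(rows), dst_grid,
                              baseline=None if jac.baseline is None
                              else jac.baseline.copy())
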