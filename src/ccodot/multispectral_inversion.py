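"""Multispectral regularized image reconstruction.

The multispectral system stacks, per wavelength λ, the sensitivity blocks
Jλ·ελ^c for each chromophore c:

    ΔA = [ Jλ1 ελ1^HbO2  Jλ1 ελ1^HHb  Jλ1 ελ1^oxCCO ]   [ ΔC_HbO2 ]
         [      ...            ...          ...     ] · [ ΔC_HHb  ]
         [ JλW ελW^HbO2  JλW ελW^HHb  JλW ελW^oxCCO ]   [ ΔC_oxCCO]

and is applied matrix-free (the dense per-chromophore blocks are never
materialized).  The image is the minimizer of

    ‖ΔA − J ΔC‖²_{Γe⁻¹} + λ_reg ‖∇(ΔC)‖²_{Γx⁻¹},

a first-order Tikhonov functional in which Γx⁻¹ = diag(C_b)⁻² spheres the
solution space by each chromophore's background concentration, so the
smoothness penalty acts equally on HbO2, HHb and oxCCO despite their very
different physiological scales.  Concretely the solver works on sphered
unknowns z = ΔC / C_b and minimizes ‖ΔA − (J S) z‖² + λ_reg ‖L z‖² with
S = diag(C_b) and L the forward-difference gradient, via LSQR on the
augmented system [J S; √λ_reg L].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, lsqr
from scipy.spatial import cKDTree

from .forward_model import Grid, WavelengthJacobian

__all__ = [
    "MultispectralSystem",
    "ReconstructionConfig",
    "ConcentrationImage",
    "assemble",
    "gradient_operator",
    "reconstruct",
    "lcurve_select",
    "surface_project",
]

DEFAULT_BACKGROUND_UM = {"HbO2": 56.0, "HHb": 24.0, "oxCCO": 12.8}


class MultispectralSystem:
    """Matrix-free stacked multispectral operator.

    Rows are grouped by wavelength (all channels of λ1, then λ2, …);
    columns are grouped by chromophore (all voxels of chromophore 1, …).
    """

    def __init__(self, jacobians: list[WavelengthJacobian], E: np.ndarray,
                 chromophores: list[str]):
        E = np.asarray(E, dtype=float)
        if E.ndim != 2 or E.shape[0] != len(jacobians):
            raise ValueError(
                f"extinction matrix rows ({E.shape[0]}) must match the number "
                f"of Jacobians ({len(jacobians)})"
            )
        if E.shape[1] != len(chromophores):
            raise ValueError("extinction matrix columns must match chromophores")
        n_vox = {j.grid.n_voxels for j in jacobians}
        n_ch = {j.n_channels for j in jacobians}
        if len(n_vox) != 1 or len(n_ch) != 1:
            raise ValueError("Jacobians must share voxel and channel counts")
        self.jacobians = list(jacobians)
        self.E = E
        self.chromophores = list(chromophores)
        self.n_voxels = n_vox.pop()
        self.n_channels = n_ch.pop()
        self.grid = jacobians[0].grid

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.array([j.wavelength_nm for j in self.jacobians])

    @property
    def n_wavelengths(self) -> int:
        return len(self.jacobians)

    @property
    def n_chromophores(self) -> int:
        return len(self.chromophores)

    @property
    def shape(self):
        return (self.n_channels * self.n_wavelengths,
                self.n_voxels * self.n_chromophores)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Apply the stacked operator: x (voxels × chrom, flat) → ΔA (flat)."""
        X = np.asarray(x, dtype=float).reshape(self.n_chromophores, self.n_voxels)
        # per wavelength: Δμa_λ = Σ_c ε_λc x_c, then Jλ @ Δμa_λ
        mua = self.E @ X  # (n_wl, n_vox)
        out = np.empty((self.n_wavelengths, self.n_channels))
        for w, jac in enumerate(self.jacobians):
            out[w] = jac.matrix @ mua[w]
        return out.ravel()

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        Y = np.asarray(y, dtype=float).reshape(self.n_wavelengths, self.n_channels)
        g = np.empty((self.n_wavelengths, self.n_voxels))
        for w, jac in enumerate(self.jacobians):
            g[w] = jac.matrix.T @ Y[w]
        return (self.E.T @ g).ravel()

    def as_operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self.matvec,
                              rmatvec=self.rmatvec, dtype=float)

    def to_dense(self) -> np.ndarray:
        """Explicit stacked matrix (toy systems / oracles only)."""
        blocks = [[jac.matrix * self.E[w, c] for c in range(self.n_chromophores)]
                  for w, jac in enumerate(self.jacobians)]
        return np.block(blocks)

    def stack_frame(self, dA_frame: np.ndarray) -> np.ndarray:
        """Flatten a (channel × wavelength) frame into the stacked row order."""
        dA_frame = np.asarray(dA_frame, dtype=float)
        if dA_frame.shape != (self.n_channels, self.n_wavelengths):
            raise ValueError(
                f"frame shape {dA_frame.shape} != "
                f"({self.n_channels}, {self.n_wavelengths})"
            )
        return dA_frame.T.ravel()

    def unstack(self, y: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`stack_frame`: flat vector → (channel × wavelength)."""
        return np.asarray(y).reshape(self.n_wavelengths, self.n_channels).T


def assemble(jacobians, E, chromophores) -> MultispectralSystem:
    """Build the stacked multispectral operator (matrix-free)."""
    return MultispectralSystem(jacobians, E, chromophores)


@dataclass
class ReconstructionConfig:
    """Inverse-problem settings.

    ``hyperparameter`` is the Tikhonov weight λ_reg (default 1e-4, chosen
    by L-curve inspection); ``background_uM`` are the assumed background
    concentrations used for sphering (HbO2 56, HHb 24, oxCCO 12.8 µM, the
    oxCCO value reflecting visual-cortex enzyme concentration);
    ``noise_cov_diag`` is the diagonal of Γe (identity by default).  LSQR
    stops at ``tolerance`` or after ``max_iterations``.
    """

    hyperparameter: float = 1e-4
    background_uM: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND_UM))
    noise_cov_diag: np.ndarray | None = None
    max_iterations: int = 50
    tolerance: float = 1e-5
    chromophores: tuple = ("HbO2", "HHb", "oxCCO")

    def __post_init__(self):
        if self.hyperparameter <= 0:
            raise ValueError("regularization hyperparameter must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if len(self.chromophores) not in (2, 3):
            raise ValueError("chromophore set must have 2 or 3 members")
        for c in self.chromophores:
            if c not in self.background_uM:
                raise ValueError(f"no background concentration for {c!r}")
            if self.background_uM[c] <= 0:
                raise ValueError("background concentrations must be positive")

    def sphering(self) -> np.ndarray:
        """Per-chromophore sphering scales C_b (µM), in chromophore order."""
        return np.array([self.background_uM[c] for c in self.chromophores])


@dataclass
class ConcentrationImage:
    """Per-chromophore voxel images of concentration change (µM)."""

    data: np.ndarray  # (n_chromophores, nx, ny, nz)
    chromophores: list
    grid: Grid
    time_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.chromophores), *self.grid.shape):
            raise ValueError("image shape must be (n_chromophores, *grid.shape)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")

    def flat(self) -> np.ndarray:
        """Chromophore-stacked flat vector matching the system columns."""
        return self.data.reshape(len(self.chromophores), -1).ravel()

    def __getitem__(self, chromophore: str) -> np.ndarray:
        return self.data[self.chromophores.index(chromophore)]

    def to_nifti(self, directory, prefix="dconc") -> list:
        import nibabel as nib
        paths = []
        aff = np.diag([self.grid.spacing] * 3 + [1.0])
        aff[:3, 3] = self.grid.origin
        for i, c in enumerate(self.chromophores):
            t = "" if self.time_s is None else f"_t{self.time_s:g}s"
            p = f"{directory}/{prefix}_{c}{t}.nii"
            nib.save(nib.Nifti1Image(self.data[i].astype(np.float32), aff), p)
            paths.append(p)
        sidecar = f"{directory}/{prefix}_meta.json"
        with open(sidecar, "w") as f:
            json.dump({"units": "uM", "chromophores": self.chromophores,
                       "time_s": self.time_s, **self.meta}, f, indent=2)
        return paths + [sidecar]


def gradient_operator(grid_shape, n_chromophores: int = 1) -> sparse.csr_matrix:
    """First-order forward-difference gradient with reflective boundaries.

    Per chromophore and axis, rows are (x[i+1] − x[i]) / 1 for interior
    faces; the last plane along each axis has no row (zero-gradient
    boundary).  The block-diagonal operator repeats over chromophores.
    """
    shape = tuple(grid_shape)
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    blocks = []
    for ax in range(3):
        if shape[ax] < 2:
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        ia = idx[tuple(sl_a)].ravel()
        ib = idx[tuple(sl_b)].ravel()
        m = ia.size
        rows = np.repeat(np.arange(m), 2)
        cols = np.column_stack([ia, ib]).ravel()
        vals = np.tile([-1.0, 1.0], m)
        blocks.append(sparse.csr_matrix((vals, (rows, cols)), shape=(m, n)))
    L1 = sparse.vstack(blocks).tocsr()
    if n_chromophores == 1:
        return L1
    return sparse.block_diag([L1] * n_chromophores).tocsr()


def _augmented_solve(system: MultispectralSystem, b: np.ndarray,
                     config: ReconstructionConfig, lam: float):
    """LSQR solve of min ‖b − (J S) z‖² + lam ‖L z‖²; returns (x_phys, info)."""
    nc, nv = system.n_chromophores, system.n_voxels
    S = np.repeat(config.sphering(), nv)
    L = gradient_operator(system.grid.shape, nc)
    sqlam = np.sqrt(lam)
    m = system.shape[0]
    if config.noise_cov_diag is not None:
        wts = 1.0 / np.sqrt(np.asarray(config.noise_cov_diag, dtype=float))
        if wts.shape != (m,):
            raise ValueError("noise covariance diagonal has wrong length")
    else:
        wts = None

    def mv(z):
        top = system.matvec(S * z)
        if wts is not None:
            top = wts * top
        return np.concatenate([top, sqlam * (L @ z)])

    def rmv(y):
        y1, y2 = y[:m], y[m:]
        if wts is not None:
            y1 = wts * y1
        return S * system.rmatvec(y1) + sqlam * (L.T @ y2)

    op = LinearOperator((m + L.shape[0], nc * nv), matvec=mv, rmatvec=rmv,
                        dtype=float)
    rhs = np.concatenate([wts * b if wts is not None else b,
                          np.zeros(L.shape[0])])
    sol = lsqr(op, rhs, atol=config.tolerance, btol=config.tolerance,
               iter_lim=config.max_iterations)
    z = sol[0]
    if not np.all(np.isfinite(z)):
        raise RuntimeError(
            f"LSQR produced non-finite solution (istop={sol[1]}, itn={sol[2]})")
    info = {"istop": int(sol[1]), "iterations": int(sol[2]),
            "residual_norm": float(np.linalg.norm(b - system.matvec(S * z))),
            "penalty_norm": float(np.linalg.norm(L @ z)),
            "hyperparameter": float(lam)}
    return S * z, info


def reconstruct(dA, system: MultispectralSystem,
                config: ReconstructionConfig | None = None,
                time_s: float | None = None) -> ConcentrationImage:
    """Reconstruct a concentration-change image from one attenuation frame.

    Parameters
    ----------
    dA
        Either a stacked vector (wavelength-major, matching the system
        rows) or a (channel × wavelength) frame.
    system
        Assembled multispectral operator.
    config
        Solver settings; defaults reproduce the standard configuration
        (λ_reg 1e-4, LSQR ≤ 50 iterations, tolerance 1e-5).

    The iterative solver starts from zero, so the result is deterministic;
    ΔA = 0 returns an exactly zero image.
    """
    if config is None:
        config = ReconstructionConfig(
            chromophores=tuple(system.chromophores))
    if tuple(config.chromophores) != tuple(system.chromophores):
        raise ValueError("config and system chromophore sets differ")
    b = np.asarray(dA, dtype=float)
    if b.ndim == 2:
        b = system.stack_frame(b)
    if b.shape != (system.shape[0],):
        raise ValueError("attenuation vector length mismatch")
    if not np.all(np.isfinite(b)):
        raise ValueError("attenuation data must be finite")
    if not b.any():
        x = np.zeros(system.shape[1])
        info = {"istop": 0, "iterations": 0, "residual_norm": 0.0,
                "penalty_norm": 0.0, "hyperparameter": config.hyperparameter}
    else:
        x, info = _augmented_solve(system, b, config, config.hyperparameter)
    data = x.reshape(system.n_chromophores, *system.grid.shape)
    return ConcentrationImage(data, list(system.chromophores), system.grid,
                              time_s=time_s, meta=info)


def lcurve_select(dA, system: MultispectralSystem,
                  config: ReconstructionConfig, lambda_grid) -> tuple[float, dict]:
    """Choose λ_reg at the maximum-curvature point of the L-curve.

    Solves the inverse problem over ``lambda_grid`` (≥ 5 points spanning at
    least two decades), records the data-residual norm ρ(λ) and the penalty
    norm η(λ), and returns the grid λ maximizing the curvature of the
    (log ρ, log η) curve (finite-difference curvature in log λ).
    """
    lam = np.sort(np.asarray(lambda_grid, dtype=float))
    if lam.size < 5 or np.any(lam <= 0):
        raise ValueError("lambda grid must have >= 5 positive points")
    if lam[-1] / lam[0] < 100.0:
        raise ValueError("lambda grid must span at least two decades")
    b = np.asarray(dA, dtype=float)
    if b.ndim == 2:
        b = system.stack_frame(b)
    rho, eta = [], []
    for lv in lam:
        try:
            _, info = _augmented_solve(system, b, config, lv)
        except Exception as err:
            raise RuntimeError(
                f"solver failed at lambda={lv:g}; partial L-curve computed "
                f"for {len(rho)} points") from err
        rho.append(info["residual_norm"])
        eta.append(info["penalty_norm"])
    rho, eta = np.array(rho), np.array(eta)
    t = np.log(lam)
    x, y = np.log(rho), np.log(eta)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    curvature = (dx * ddy - dy * ddx) / np.power(dx ** 2 + dy ** 2, 1.5)
    best = int(np.argmax(curvature))
    curve = {"lambda": lam, "residual_norm": rho, "penalty_norm": eta,
             "curvature": curvature}
    return float(lam[best]), curve


def surface_project(volume: ConcentrationImage, surface_nodes,
                    radius_mm: float = 3.0):
    """Average voxel values within ``radius_mm`` of each surface node.

    Returns (values, missing) where ``values[c, k]`` is the mean image
    value of chromophore c over voxels whose centers lie within the radius
    of node k, and ``missing[k]`` marks nodes with no voxel in range
    (their values are NaN, never silently zero).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    nodes = np.atleast_2d(np.asarray(surface_nodes, dtype=float))
    centers = volume.grid.centers()
    tree = cKDTree(centers)
    groups = tree.query_ball_point(nodes, r=radius_mm)
    nc = len(volume.chromophores)
    vals = np.full((nc, len(nodes)), np.nan)
    missing = np.zeros(len(nodes), dtype=bool)
    flat = volume.data.reshape(nc, -1)
    for k, g in enumerate(groups):
        if len(g) == 0:
            missing[k] = True
        else:
            vals[:, k] = flat[:, g].mean(axis=1)
    return vals, missing
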