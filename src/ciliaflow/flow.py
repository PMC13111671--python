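"""Grid vector fields, flow-map integration and FTLE fields.

A recording's tracks are summarized into one steady velocity field on a
regular grid (default 30×30) by Laplacian-regularized linear least squares
with a bilinear basis: the field minimizes

    (1/N) Σ_steps ||v_obs − v_bilinear(midpoint)||²
        + w · (1/M) Σ_nodes ||(L u, L v)||²

where N is the number of track steps, M the number of grid nodes, L the
lattice graph Laplacian and w the smoothing weight (default 0.5).  The
smoothing term fills cells containing no track data, so the field is finite
everywhere; for w > 0 with any data the system is positive definite and
the solution unique.

Flow maps are integrated from every grid node with classical 4th-order
Runge–Kutta on the bilinearly interpolated field; the finite-time Lyapunov
exponent (FTLE) at each node is ln √λ_max(C) / |T| where
C = (∇Φ)ᵀ(∇Φ) is the Cauchy–Green tensor of the flow map Φ over horizon
T, with ∇Φ by central finite differences on the seed grid.  Ridges of the
FTLE field approximate transport barriers (Lagrangian coherent structures).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from sklearn.base import BaseEstimator

from .io import TrackSet

__all__ = [
    "GridVectorField",
    "FTLEField",
    "FTLEParams",
    "fit_grid_vector_field",
    "sample_field_bilinear",
    "integrate_flow_map",
    "compute_ftle",
    "ftle_per_recording",
]


@dataclass(frozen=True)
class FTLEParams:
    """Flow-map integration settings.

    ``dt_frames`` is the step in (retained) frames; the seconds-per-frame
    conversion comes from the TrackSet metadata (subsample_factor / fps).
    ``n_steps`` may exceed the recording length: the horizon T = n_steps·dt
    only needs to cover the vector field, not the video.
    """

    n_steps: int = 20000
    dt_frames: float = 5.0
    boundary_mode: str = "clamp_velocity_zero"  # or "freeze_position"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt_frames <= 0:
            raise ValueError("dt_frames must be > 0")
        if self.boundary_mode not in ("clamp_velocity_zero", "freeze_position"):
            raise ValueError("unknown boundary_mode")


@dataclass
class FTLEField:
    """Scalar FTLE values (1/s) on the field's grid, with horizon T (s).

    ``valid_mask`` marks nodes where the FTLE is quantitatively meaningful:
    neither the node's own trajectory nor any trajectory entering its
    finite-difference stencil left the domain during integration.  Values
    outside the mask are boundary-halted artefacts (trajectories stop where
    the field ends) and should be read qualitatively only.
    """

    values: np.ndarray  # (ny, nx)
    horizon_s: float
    x_nodes: np.ndarray
    y_nodes: np.ndarray
    valid_mask: np.ndarray | None = None

    def to_long_dataframe(self) -> pd.DataFrame:
        XX, YY = np.meshgrid(self.x_nodes, self.y_nodes)
        return pd.DataFrame(
            {"x": XX.ravel(), "y": YY.ravel(), "ftle": self.values.ravel()}
        )


class GridVectorField(BaseEstimator):
    """Steady velocity field on a regular grid, fitted from track steps.

    scikit-learn style: ``fit(trackset)`` estimates node velocities,
    ``predict(points)`` evaluates the field by bilinear interpolation.

    Parameters
    ----------
    grid_nx, grid_ny : int, default 30
        Grid resolution (nodes per axis).
    smoothing_weight : float, default 0.5
        Weight of the discrete-Laplacian smoothness energy.
    domain : (x_min, x_max, y_min, y_max) or None
        Field rectangle in µm; defaults to the tracks' bounding box padded
        by 5 %.

    Attributes
    ----------
    u_, v_ : (ny, nx) node velocity components, µm/s
    x_nodes_, y_nodes_ : grid node coordinates
    residual_ : normalized data-term value at the solution
    smoothness_ : normalized smoothness-energy value at the solution
    n_observations_ : number of track steps used
    """

    def __init__(
        self,
        grid_nx: int = 30,
        grid_ny: int = 30,
        smoothing_weight: float = 0.5,
        domain: tuple[float, float, float, float] | None = None,
    ):
        self.grid_nx = grid_nx
        self.grid_ny = grid_ny
        self.smoothing_weight = smoothing_weight
        self.domain = domain

    # ------------------------------------------------------------------ fit
    def fit(self, X: TrackSet, y=None) -> "GridVectorField":
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2x2")
        if self.smoothing_weight < 0:
            raise ValueError("smoothing_weight must be >= 0")
        mid, vel = _observations(X)
        if self.domain is not None:
            dom = tuple(map(float, self.domain))
        else:
            dom = X.bounding_box(pad_frac=0.05)
        self.domain_ = dom
        nx, ny = self.grid_nx, self.grid_ny
        self.x_nodes_ = np.linspace(dom[0], dom[1], nx)
        self.y_nodes_ = np.linspace(dom[2], dom[3], ny)

        inside = (
            (mid[:, 0] >= dom[0])
            & (mid[:, 0] <= dom[1])
            & (mid[:, 1] >= dom[2])
            & (mid[:, 1] <= dom[3])
        )
        mid, vel = mid[inside], vel[inside]
        N = len(mid)
        if N == 0:
            raise ValueError("no in-domain track steps: cannot fit a vector field")

        A = _bilinear_design(mid, self.x_nodes_, self.y_nodes_)
        M = nx * ny
        if self.smoothing_weight == 0:
            support = np.asarray((A != 0).sum(axis=0)).ravel()
            if (support == 0).any():
                raise ValueError(
                    "smoothing_weight=0 with grid nodes unsupported by data: "
                    "the system is singular; use a positive smoothing_weight"
                )
        L = _lattice_laplacian(nx, ny)
        lhs = (A.T @ A) / N + (self.smoothing_weight / M) * (L.T @ L)
        solver = splu(sp.csc_matrix(lhs))
        bu = A.T @ vel[:, 0] / N
        bv = A.T @ vel[:, 1] / N
        wu = solver.solve(bu)
        wv = solver.solve(bv)
        self.u_ = wu.reshape(ny, nx)
        self.v_ = wv.reshape(ny, nx)
        self.n_observations_ = N
        ru = A @ wu - vel[:, 0]
        rv = A @ wv - vel[:, 1]
        self.residual_ = float((ru @ ru + rv @ rv) / N)
        self.smoothness_ = float(((L @ wu) @ (L @ wu) + (L @ wv) @ (L @ wv)) / M)
        self.frame_dt_ = X.frame_dt
        return self

    @classmethod
    def from_function(
        cls,
        func,
        domain: tuple[float, float, float, float],
        grid_nx: int = 30,
        grid_ny: int = 30,
        frame_dt: float = 1.0,
    ) -> "GridVectorField":
        """Build a field by sampling an analytic velocity function at the
        grid nodes (bilinear interpolation is exact for affine fields)."""
        obj = cls(grid_nx=grid_nx, grid_ny=grid_ny, domain=domain)
        obj.domain_ = tuple(map(float, domain))
        obj.x_nodes_ = np.linspace(domain[0], domain[1], grid_nx)
        obj.y_nodes_ = np.linspace(domain[2], domain[3], grid_ny)
        XX, YY = np.meshgrid(obj.x_nodes_, obj.y_nodes_)
        V = func(np.column_stack([XX.ravel(), YY.ravel()]))
        V = np.asarray(V, dtype=np.float64).reshape(grid_ny, grid_nx, 2)
        obj.u_ = V[:, :, 0]
        obj.v_ = V[:, :, 1]
        obj.n_observations_ = 0
        obj.residual_ = 0.0
        obj.smoothness_ = float("nan")
        obj.frame_dt_ = frame_dt
        return obj

    # ------------------------------------------------------------ evaluate
    def predict(self, points: np.ndarray, outside: str = "zero") -> np.ndarray:
        """Bilinear velocity at each point (exact at grid nodes).

        ``outside``: "zero" returns (0, 0) outside the domain (the default
        boundary handling during integration); "clip" evaluates at the
        nearest in-domain point.
        """
        points = np.asarray(points, dtype=np.float64)
        single = points.ndim == 1
        P = np.atleast_2d(points)
        if np.isnan(P).any():
            raise ValueError("NaN point passed to field evaluation")
        out = _bilinear_eval(P, self.x_nodes_, self.y_nodes_, self.u_, self.v_, outside)
        return out[0] if single else out

    def speed(self) -> np.ndarray:
        return np.hypot(self.u_, self.v_)

    # ---------------------------------------------------------------- I/O
    def to_long_dataframe(self) -> pd.DataFrame:
        XX, YY = np.meshgrid(self.x_nodes_, self.y_nodes_)
        return pd.DataFrame(
            {
                "x": XX.ravel(),
                "y": YY.ravel(),
                "u": self.u_.ravel(),
                "v": self.v_.ravel(),
            }
        )

    def write_matrix_text(self, path: str | Path) -> Path:
        """Delimited text export: header block (domain, shape, units) then
        the u and v node matrices."""
        path = Path(path)
        with open(path, "w") as fh:
            d = self.domain_
            fh.write("# grid vector field\n")
            fh.write(f"# domain_um {d[0]:.9g} {d[1]:.9g} {d[2]:.9g} {d[3]:.9g}\n")
            fh.write(f"# shape {self.u_.shape[0]} {self.u_.shape[1]}\n")
            fh.write("# units um_per_s\n")
            fh.write("# component u\n")
            np.savetxt(fh, self.u_, fmt="%.9e")
            fh.write("# component v\n")
            np.savetxt(fh, self.v_, fmt="%.9e")
        return path


def _observations(tracks: TrackSet) -> tuple[np.ndarray, np.ndarray]:
    """Step midpoints and finite-difference velocities from all tracks."""
    mids, vels = [], []
    for t in tracks:
        if t.n_points < 2:
            continue
        dt = np.diff(t.frames) * tracks.frame_dt
        step = np.diff(t.xy, axis=0)
        mids.append(0.5 * (t.xy[:-1] + t.xy[1:]))
        vels.append(step / dt[:, None])
    if not mids:
        raise ValueError("TrackSet contains no usable steps")
    return np.vstack(mids), np.vstack(vels)


def _bilinear_design(P: np.ndarray, xn: np.ndarray, yn: np.ndarray) -> sp.csr_matrix:
    """Sparse (N, nx*ny) matrix of bilinear weights at points P."""
    nx, ny = len(xn), len(yn)
    ix, tx = _cell_coords(P[:, 0], xn)
    iy, ty = _cell_coords(P[:, 1], yn)
    N = len(P)
    rows = np.repeat(np.arange(N), 4)
    cols = np.empty(4 * N, dtype=np.int64)
    vals = np.empty(4 * N)
    cols[0::4] = iy * nx + ix
    vals[0::4] = (1 - tx) * (1 - ty)
    cols[1::4] = iy * nx + ix + 1
    vals[1::4] = tx * (1 - ty)
    cols[2::4] = (iy + 1) * nx + ix
    vals[2::4] = (1 - tx) * ty
    cols[3::4] = (iy + 1) * nx + ix + 1
    vals[3::4] = tx * ty
    return sp.csr_matrix((vals, (rows, cols)), shape=(N, nx * ny))


def _cell_coords(x: np.ndarray, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Containing-cell index and in-cell fraction for a uniform grid."""
    h = nodes[1] - nodes[0]
    i = np.clip(((x - nodes[0]) / h).astype(np.int64), 0, len(nodes) - 2)
    t = (x - nodes[i]) / h
    return i, np.clip(t, 0.0, 1.0)


def _lattice_laplacian(nx: int, ny: int) -> sp.csr_matrix:
    """Graph Laplacian of the nx×ny 4-neighbour lattice (constant nullspace)."""
    idx = np.arange(nx * ny).reshape(ny, nx)
    pairs = np.vstack(
        [
            np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]),
            np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]),
        ]
    )
    M = nx * ny
    data = np.ones(len(pairs))
    Adj = sp.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(M, M))
    Adj = Adj + Adj.T
    deg = np.asarray(Adj.sum(axis=1)).ravel()
    return (sp.diags(deg) - Adj).tocsr()


def _bilinear_eval(
    P: np.ndarray,
    xn: np.ndarray,
    yn: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    outside: str,
) -> np.ndarray:
    x0, x1 = xn[0], xn[-1]
    y0, y1 = yn[0], yn[-1]
    in_dom = (P[:, 0] >= x0) & (P[:, 0] <= x1) & (P[:, 1] >= y0) & (P[:, 1] <= y1)
    Q = P.copy()
    Q[:, 0] = np.clip(Q[:, 0], x0, x1)
    Q[:, 1] = np.clip(Q[:, 1], y0, y1)
    ix, tx = _cell_coords(Q[:, 0], xn)
    iy, ty = _cell_coords(Q[:, 1], yn)
    w00 = (1 - tx) * (1 - ty)
    w10 = tx * (1 - ty)
    w01 = (1 - tx) * ty
    w11 = tx * ty
    out = np.empty_like(P)
    for comp, arr in ((0, u), (1, v)):
        out[:, comp] = (
            w00 * arr[iy, ix]
            + w10 * arr[iy, ix + 1]
            + w01 * arr[iy + 1, ix]
            + w11 * arr[iy + 1, ix + 1]
        )
    if outside == "zero":
        out[~in_dom] = 0.0
    elif outside != "clip":
        raise ValueError("outside must be 'zero' or 'clip'")
    return out


def fit_grid_vector_field(
    tracks: TrackSet,
    grid_nx: int = 30,
    grid_ny: int = 30,
    smoothing_weight: float = 0.5,
    domain: tuple[float, float, float, float] | None = None,
) -> GridVectorField:
    """Fit the regularized grid vector field to a TrackSet (thin wrapper
    over :class:`GridVectorField`)."""
    return GridVectorField(grid_nx, grid_ny, smoothing_weight, domain).fit(tracks)


def sample_field_bilinear(field: GridVectorField, points: np.ndarray) -> np.ndarray:
    """Bilinear field evaluation at points inside the domain."""
    return field.predict(points, outside="clip")


def integrate_flow_map(
    field: GridVectorField,
    seeds: np.ndarray,
    params: FTLEParams = FTLEParams(),
    dt_s: float | None = None,
    return_exited: bool = False,
) -> np.ndarray:
    """Advect seed points through the field with classical RK4.

    ``dt_s`` overrides the frames→seconds conversion
    (dt = dt_frames · frame_dt) when given.  Boundary handling follows
    ``params.boundary_mode``: ``clamp_velocity_zero`` sets the velocity to
    zero outside the domain (trajectories halt at the boundary);
    ``freeze_position`` stops updating a trajectory once it exits.

    Returns the end position of every seed; with ``return_exited`` also a
    boolean array marking trajectories that left the domain at any step.
    """
    dt = params.dt_frames * field.frame_dt_ if dt_s is None else dt_s
    pos = np.atleast_2d(np.asarray(seeds, dtype=np.float64)).copy()
    d = field.domain_
    freeze = params.boundary_mode == "freeze_position"
    active = np.ones(len(pos), dtype=bool)
    exited = np.zeros(len(pos), dtype=bool)

    def vel(p):
        return field.predict(p, outside="zero")

    def inside(p):
        return (
            (p[:, 0] >= d[0]) & (p[:, 0] <= d[1]) & (p[:, 1] >= d[2]) & (p[:, 1] <= d[3])
        )

    for _ in range(params.n_steps):
        p = pos[active]
        if len(p) == 0:
            break
        k1 = vel(p)
        k2 = vel(p + 0.5 * dt * k1)
        k3 = vel(p + 0.5 * dt * k2)
        k4 = vel(p + dt * k3)
        newp = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(newp).all():
            bad = np.flatnonzero(active)[~np.isfinite(newp).all(axis=1)][0]
            raise FloatingPointError(f"non-finite velocity while integrating seed {bad}")
        pos[active] = newp
        idx = np.flatnonzero(active)
        out_now = ~inside(newp)
        exited[idx[out_now]] = True
        if freeze:
            active[idx[out_now]] = False
    if return_exited:
        return pos, exited
    return pos


def compute_ftle(
    field: GridVectorField,
    params: FTLEParams = FTLEParams(),
    dt_s: float | None = None,
) -> FTLEField:
    """FTLE scalar field on the grid from the forward flow map.

    Every grid node seeds one trajectory; ∇Φ is taken by second-order
    finite differences over neighbouring seeds (central in the interior,
    one-sided at the domain edges), C = (∇Φ)ᵀ(∇Φ), and
    FTLE = ln √λ_max(C) / |T| with T = n_steps·dt.
    """
    xn, yn = field.x_nodes_, field.y_nodes_
    if len(xn) < 3 or len(yn) < 3 or xn[1] == xn[0] or yn[1] == yn[0]:
        raise ValueError("degenerate grid for FTLE computation")
    XX, YY = np.meshgrid(xn, yn)
    seeds = np.column_stack([XX.ravel(), YY.ravel()])
    dt = params.dt_frames * field.frame_dt_ if dt_s is None else dt_s
    T = params.n_steps * dt
    ends, exited = integrate_flow_map(field, seeds, params, dt_s=dt, return_exited=True)
    ny, nx = len(yn), len(xn)
    Phi_x = ends[:, 0].reshape(ny, nx)
    Phi_y = ends[:, 1].reshape(ny, nx)
    # np.gradient: central differences inside, second-order one-sided at edges
    dPhix_dy, dPhix_dx = np.gradient(Phi_x, yn, xn, edge_order=2)
    dPhiy_dy, dPhiy_dx = np.gradient(Phi_y, yn, xn, edge_order=2)
    a = dPhix_dx**2 + dPhiy_dx**2
    b = dPhix_dx * dPhix_dy + dPhiy_dx * dPhiy_dy
    c = dPhix_dy**2 + dPhiy_dy**2
    lam_max = 0.5 * (a + c) + np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b**2, 0.0))
    lam_max = np.maximum(lam_max, 1e-300)
    ftle = np.log(np.sqrt(lam_max)) / abs(T)
    # a node's FTLE is quantitative only if no trajectory in its stencil
    # halted at the boundary
    stayed = ~exited.reshape(ny, nx)
    valid = stayed.copy()
    valid[1:, :] &= stayed[:-1, :]
    valid[:-1, :] &= stayed[1:, :]
    valid[:, 1:] &= stayed[:, :-1]
    valid[:, :-1] &= stayed[:, 1:]
    return FTLEField(values=ftle, horizon_s=float(T), x_nodes=xn, y_nodes=yn, valid_mask=valid)


def ftle_per_recording(
    tracks: TrackSet,
    grid_nx: int = 30,
    grid_ny: int = 30,
    smoothing_weight: float = 0.5,
    domain: tuple[float, float, float, float] | None = None,
    ftle_params: FTLEParams = FTLEParams(),
    backward: bool = False,
) -> tuple[GridVectorField, FTLEField]:
    """One recording's full flow-structure analysis: fit the grid field,
    then compute its FTLE field.  ``backward=True`` negates the field
    before integration (backward-time FTLE)."""
    field = fit_grid_vector_field(tracks, grid_nx, grid_ny, smoothing_weight, domain)
    if backward:
        field.u_ = -field.u_
        field.v_ = -field.v_
        ftle = compute_ftle(field, ftle_params)
        field.u_ = -field.u_
        field.v_ = -field.v_
    else:
        ftle = compute_ftle(field, ftle_params)
    return field, ftle
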