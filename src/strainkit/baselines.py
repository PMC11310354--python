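"""Classical subset-based texture-correlation strain estimators.

Two benchmark methods are provided:

* :func:`dic_track` — subset DIC: integer normalized-cross-correlation
  search, Gauss-Newton refinement of a linear (6-parameter affine) shape
  function per subset, displacement recorded at each subset center, and
  strain obtained by least-squares plane fits of the displacement over
  each center's 3x3 neighborhood.
* :func:`dde_track` — direct deformation estimation: the same per-subset
  affine registration, but strain is read directly from the gradient
  part F of the converged affine (eps = (F + F^T)/2 - I), with no
  displacement differentiation step.

Both return dense fields by linear interpolation of the per-center
values, valid only inside the convex hull of converged centers — unlike
the network, which predicts at every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from skimage.feature import match_template

from .types import StrainField

__all__ = ["SubsetGrid", "dic_track", "dde_track", "tune_grid"]


@dataclass(frozen=True)
class SubsetGrid:
    """Subset layout and matching hyperparameters.

    ``subset_size`` is the odd side length of each square subset (px),
    ``step`` the center spacing, ``search_range`` the half-width of the
    integer NCC search, and ``corr_threshold`` the minimum NCC peak for a
    subset to count as valid.
    """

    subset_size: int = 21
    step: int = 8
    search_range: int = 12
    corr_threshold: float = 0.5
    max_iters: int = 50
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.subset_size < 11 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 11")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def centers(self, shape: tuple[int, int]) -> np.ndarray:
        """Subset centers (row, col) fitting inside the image."""
        half = self.subset_size // 2
        h, w = shape
        rows = np.arange(half, h - half, self.step)
        cols = np.arange(half, w - half, self.step)
        if rows.size == 0 or cols.size == 0:
            raise ValueError("image too small for this subset grid")
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _integer_search(
    a: np.ndarray, b: np.ndarray, cy: int, cx: int, grid: SubsetGrid
) -> tuple[float, float, float]:
    """Integer-pixel NCC match of the subset around (cy, cx)."""
    half = grid.subset_size // 2
    subset = a[cy - half: cy + half + 1, cx - half: cx + half + 1]
    if subset.std() == 0:
        return 0.0, 0.0, -1.0
    y0 = max(cy - half - grid.search_range, 0)
    y1 = min(cy + half + grid.search_range + 1, b.shape[0])
    x0 = max(cx - half - grid.search_range, 0)
    x1 = min(cx + half + grid.search_range + 1, b.shape[1])
    region = b[y0:y1, x0:x1]
    if region.shape[0] < subset.shape[0] or region.shape[1] < subset.shape[1]:
        return 0.0, 0.0, -1.0
    ncc = match_template(region, subset)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    v0 = (y0 + iy + half) - cy
    u0 = (x0 + ix + half) - cx
    return float(u0), float(v0), float(ncc[iy, ix])


def _refine_affine(
    subset: np.ndarray,
    b_spline: np.ndarray,
    grads: tuple[np.ndarray, np.ndarray],
    cy: int,
    cx: int,
    u0: float,
    v0: float,
    grid: SubsetGrid,
) -> tuple[np.ndarray, bool]:
    """Gauss-Newton SSD minimization of a 6-parameter affine warp.

    Parameters p = (u, v, du/dx, du/dy, dv/dx, dv/dy); sampling of the
    deformed frame and its gradients uses precomputed cubic-spline
    coefficients.
    """
    half = grid.subset_size // 2
    dy, dx = np.mgrid[-half: half + 1, -half: half + 1].astype(float)
    dxf, dyf = dx.ravel(), dy.ravel()
    target = subset.ravel()
    bx, by = grads
    p = np.array([u0, v0, 0.0, 0.0, 0.0, 0.0])
    for _ in range(grid.max_iters):
        u, v, ux, uy, vx, vy = p
        xs = cx + dxf + u + ux * dxf + uy * dyf
        ys = cy + dyf + v + vx * dxf + vy * dyf
        coords = [ys, xs]
        # mirror mode matches the boundary handling of spline_filter
        samp = ndimage.map_coordinates(b_spline, coords, order=3,
                                       mode="mirror", prefilter=False)
        gx = ndimage.map_coordinates(bx, coords, order=1, mode="mirror")
        gy = ndimage.map_coordinates(by, coords, order=1, mode="mirror")
        r = samp - target
        jac = np.stack(
            [gx, gy, gx * dxf, gx * dyf, gy * dxf, gy * dyf], axis=1
        )
        delta, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        p = p + delta
        if abs(p[0]) > grid.search_range + grid.subset_size:
            return p, False
        if max(abs(delta[0]), abs(delta[1])) < grid.tol:
            return p, True
    return p, False


def _match_all(
    frame_a: np.ndarray, frame_b: np.ndarray, grid: SubsetGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine parameters and validity at every subset center."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    centers = grid.centers(a.shape)
    b_spline = ndimage.spline_filter(b, order=3)
    by, bx = np.gradient(b)
    half = grid.subset_size // 2

    params = np.zeros((len(centers), 6))
    valid = np.zeros(len(centers), dtype=bool)
    for i, (cy, cx) in enumerate(centers):
        u0, v0, peak = _integer_search(a, b, cy, cx, grid)
        if peak < grid.corr_threshold:
            continue
        subset = a[cy - half: cy + half + 1, cx - half: cx + half + 1]
        p, ok = _refine_affine(subset, b_spline, (bx, by), cy, cx,
                               u0, v0, grid)
        params[i] = p
        valid[i] = ok
    return centers, params, valid


def _dense_field(
    centers: np.ndarray,
    strains: np.ndarray,
    valid: np.ndarray,
    shape: tuple[int, int],
) -> StrainField:
    """Linear interpolation of per-center strains onto the pixel grid."""
    h, w = shape
    comps = np.full((3, h, w), np.nan)
    if valid.sum() >= 3:
        yy, xx = np.mgrid[0:h, 0:w]
        pts = centers[valid][:, ::-1]  # (x, y) for griddata
        for c in range(3):
            comps[c] = griddata(pts, strains[valid, c], (xx, yy),
                                method="linear")
    mask = np.all(np.isfinite(comps), axis=0)
    comps = np.nan_to_num(comps)
    return StrainField(comps[0], comps[1], comps[2], mask)


def dic_track(
    frame_a: np.ndarray, frame_b: np.ndarray, grid: SubsetGrid | None = None
) -> StrainField:
    """Subset DIC strain field between two frames.

    Displacements come from the affine matches; strain at each center is
    the slope of a least-squares plane fit of (u, v) over the center's
    3x3 neighbor centers, then interpolated to a dense field.
    """
    grid = grid or SubsetGrid()
    centers, params, valid = _match_all(frame_a, frame_b, grid)
    rows = np.unique(centers[:, 0])
    cols = np.unique(centers[:, 1])
    nr, nc = len(rows), len(cols)
    u = params[:, 0].reshape(nr, nc)
    v = params[:, 1].reshape(nr, nc)
    ok = valid.reshape(nr, nc)

    strains = np.full((nr, nc, 3), np.nan)
    s_valid = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            i0, i1 = max(i - 1, 0), min(i + 2, nr)
            j0, j1 = max(j - 1, 0), min(j + 2, nc)
            sel = ok[i0:i1, j0:j1]
            if not ok[i, j] or sel.sum() < 4:
                continue
            ii, jj = np.mgrid[i0:i1, j0:j1]
            x = (jj[sel] - j) * grid.step
            y = (ii[sel] - i) * grid.step
            design = np.stack([np.ones_like(x), x, y], axis=1).astype(float)
            cu, *_ = np.linalg.lstsq(design, u[i0:i1, j0:j1][sel], rcond=None)
            cv, *_ = np.linalg.lstsq(design, v[i0:i1, j0:j1][sel], rcond=None)
            exx, eyy = cu[1], cv[2]
            exy = 0.5 * (cu[2] + cv[1])
            strains[i, j] = (exx, exy, eyy)
            s_valid[i, j] = True
    return _dense_field(
        centers, strains.reshape(-1, 3), s_valid.ravel(), frame_a.shape
    )


def dde_track(
    frame_a: np.ndarray, frame_b: np.ndarray, grid: SubsetGrid | None = None
) -> StrainField:
    """DDE strain field: per-subset strain from the converged affine."""
    grid = grid or SubsetGrid()
    centers, params, valid = _match_all(frame_a, frame_b, grid)
    ux, uy, vx, vy = params[:, 2], params[:, 3], params[:, 4], params[:, 5]
    strains = np.stack([ux, 0.5 * (uy + vx), vy], axis=1)
    return _dense_field(centers, strains, valid, frame_a.shape)


def tune_grid(
    method,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    truths: list[StrainField],
    subset_sizes: tuple[int, ...] = (21, 31, 41),
    steps: tuple[int, ...] = (4, 8, 16),
) -> SubsetGrid:
    """Grid-search subset and step sizes on held-out pairs with truth.

    Returns the grid with the lowest pooled median strain error; grids
    too large for the images are skipped.
    """
    from .metrics import median_strain_error, spatial_strain_error

    best = (np.inf, SubsetGrid())
    for ss in subset_sizes:
        for st in steps:
            try:
                grid = SubsetGrid(subset_size=ss, step=st)
                maps, masks = [], []
                for (a, b), truth in zip(pairs, truths):
                    pred = method(a, b, grid)
                    if not pred.valid_mask.any():
                        raise ValueError("no valid region")
                    maps.append(spatial_strain_error(pred, truth))
                    masks.append(pred.valid_mask)
                mask = np.logical_and.reduce(masks)
                if not mask.any():
                    continue
                err = median_strain_error(maps, mask)
            except ValueError:
                continue
            if err < best[0]:
                best = (err, grid)
    return best[1]
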