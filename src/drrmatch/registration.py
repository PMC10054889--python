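"""Demons deformable registration of a DRR to a reference X-ray, plus
histogram-matching preprocessing and the SSIM / correlation similarity
metrics used to score the match.

Demons variant
--------------
Thirion's original ("passive") demons: at every pixel the update force is

    v = (m - s) * grad(s) / (|grad(s)|^2 + (m - s)^2)

where ``s`` is the fixed (reference) image, ``m`` the currently warped
moving image and ``grad(s)`` the *fixed-image* gradient.  The denominator
couples intensity mismatch and edge strength so the step is bounded by
1/2 pixel per iteration; where it falls below ``intensity_eps`` the force
is zeroed.  After each additive update the displacement field is smoothed
with a Gaussian of ``sigma_px`` — the diffusion-like regularisation that
makes the method behave as an elastic-fluid compromise.  A coarse-to-fine
image pyramid handles displacements larger than a few pixels.  The whole
procedure is deterministic: identical inputs give bit-identical fields.

An optional symmetric-forces variant (averaging fixed- and moving-image
gradients) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import Image2D

__all__ = [
    "DemonsParams",
    "DisplacementField",
    "RegistrationResult",
    "histogram_match",
    "demons_register",
    "warp_image",
    "ssim",
    "corr",
]


@dataclass
class DisplacementField:
    """Dense per-pixel displacement (row, column components, in pixels)."""

    u: np.ndarray  # (2, rows, cols): u[0] row-displacement, u[1] col-displacement

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[0] != 2:
            raise ValueError("displacement field must have shape (2, rows, cols)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u[0], self.u[1])


@dataclass
class DemonsParams:
    """Tunables of the demons loop.

    ``iterations_per_level`` runs coarsest-to-finest; ``pyramid_levels``
    must equal its length.  ``sigma_px`` is the Gaussian regularisation σ
    in pixels, ``stop_tol`` the mean per-iteration update (pixels) below
    which a level stops early, and ``intensity_eps`` the denominator guard.
    """

    iterations_per_level: tuple[int, ...] = (100, 50, 25)
    sigma_px: float = 2.0
    pyramid_levels: int = 3
    stop_tol: float = 1e-3
    intensity_eps: float = 1e-9
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.pyramid_levels != len(self.iterations_per_level):
            raise ValueError("pyramid_levels must equal len(iterations_per_level)")
        if min(self.iterations_per_level) <= 0 or self.sigma_px <= 0 or self.stop_tol <= 0 or self.intensity_eps <= 0:
            raise ValueError("all demons parameters must be positive")


@dataclass
class RegistrationResult:
    warped: Image2D
    field: DisplacementField
    iterations_run: int
    ssim: float
    corr: float


# ---------------------------------------------------------------------------
# histogram matching
# ---------------------------------------------------------------------------

def histogram_match(input_img: Image2D, reference: Image2D, bins: int = 256) -> Image2D:
    """Map the input's intensity distribution onto the reference's.

    Classical histogram specification: the input is pushed through its own
    cumulative distribution (histogram equalisation, giving levels s_k),
    the reference's cumulative transform G is tabulated over the same
    number of levels, and each s_k is sent through the monotone inverse
    G^{-1}.  Output values are reference intensity levels, so the output
    range lies within the reference range.
    """
    x = np.asarray(input_img.values, dtype=float)
    r = np.asarray(reference.values, dtype=float)
    if x.max() == x.min() or r.max() == r.min():
        raise ValueError("histogram matching is undefined for constant images")
    if bins < 2:
        raise ValueError("need at least 2 bins")

    x_lo, x_hi = float(x.min()), float(x.max())
    r_lo, r_hi = float(r.min()), float(r.max())
    xi = np.clip(((x - x_lo) / (x_hi - x_lo) * bins).astype(np.int64), 0, bins - 1)
    ri = np.clip(((r - r_lo) / (r_hi - r_lo) * bins).astype(np.int64), 0, bins - 1)

    s = np.cumsum(np.bincount(xi.ravel(), minlength=bins)) / x.size  # input CDF, the s_k ladder
    G = np.cumsum(np.bincount(ri.ravel(), minlength=bins)) / r.size  # reference transform G(z_q)
    # monotone inverse: smallest reference level z with G(z) >= s_k
    z_of_s = np.searchsorted(G, s, side="left").clip(0, bins - 1)
    levels = r_lo + (np.arange(bins) + 0.5) / bins * (r_hi - r_lo)  # bin-centre intensities
    out = levels[z_of_s[xi]]
    return Image2D(out, pixel_spacing=input_img.pixel_spacing)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(moving: Image2D, fld: DisplacementField) -> Image2D:
    """Backward-warp ``moving`` by the field: out(x) = moving(x + u(x)).

    Bilinear interpolation with edge clamping, so warped values stay
    within the moving image's [min, max] (convex combinations only).
    """
    if fld.shape != moving.shape:
        raise ValueError(f"field shape {fld.shape} != image shape {moving.shape}")
    out = _warp_array(np.asarray(moving.values, dtype=float), fld.u)
    return Image2D(out, pixel_spacing=moving.pixel_spacing)


def _warp_array(values: np.ndarray, u: np.ndarray) -> np.ndarray:
    rows, cols = values.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr + u[0], cc + u[1]])
    return ndimage.map_coordinates(values, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# demons
# ---------------------------------------------------------------------------

def _downscale(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    return sm[::factor, ::factor]


def demons_register(moving: Image2D, fixed: Image2D, params: DemonsParams | None = None) -> RegistrationResult:
    """Register ``moving`` onto ``fixed`` with multi-resolution demons.

    Intensities are expected on comparable scales (the pipeline min-max
    normalises both to [0, 1] beforehand).  Returns the warped moving
    image, the dense displacement field on the fixed grid, the total
    iteration count, and SSIM / Pearson correlation between warped and
    fixed.
    """
    if params is None:
        params = DemonsParams()
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: moving {moving.shape} vs fixed {fixed.shape}")
    mv = np.asarray(moving.values, dtype=float)
    fx = np.asarray(fixed.values, dtype=float)
    if not (np.all(np.isfinite(mv)) and np.all(np.isfinite(fx))):
        raise ValueError("non-finite pixels")

    levels = params.pyramid_levels
    total_iters = 0
    u: np.ndarray | None = None
    for li in range(levels):
        factor = 2 ** (levels - 1 - li)
        fx_l = _downscale(fx, factor)
        mv_l = _downscale(mv, factor)
        if u is None:
            u = np.zeros((2,) + fx_l.shape)
        else:
            u = 2.0 * np.stack(
                [
                    _resize_to(u[0], fx_l.shape),
                    _resize_to(u[1], fx_l.shape),
                ]
            )
        gy, gx = np.gradient(fx_l)
        g2 = gy * gy + gx * gx
        for _ in range(params.iterations_per_level[li]):
            warped = _warp_array(mv_l, u)
            diff = warped - fx_l
            denom = g2 + diff * diff
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(denom >= params.intensity_eps, diff / denom, 0.0)
            if params.symmetric:
                wy, wx = np.gradient(warped)
                vy = scale * 0.5 * (gy + wy)
                vx = scale * 0.5 * (gx + wx)
            else:
                vy = scale * gy
                vx = scale * gx
            u[0] -= vy
            u[1] -= vx
            u[0] = ndimage.gaussian_filter(u[0], params.sigma_px)
            u[1] = ndimage.gaussian_filter(u[1], params.sigma_px)
            total_iters += 1
            if float(np.mean(np.hypot(vy, vx))) < params.stop_tol:
                break
    assert u is not None
    fld = DisplacementField(u)
    warped_img = Image2D(_warp_array(mv, u), pixel_spacing=fixed.pixel_spacing)
    s = ssim(warped_img, fixed)
    c = corr(warped_img, fixed) if (warped_img.values.std() > 0 and fx.std() > 0) else 0.0
    return RegistrationResult(warped_img, fld, total_iters, s, c)


def _resize_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(arr, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def ssim(
    x: Image2D | np.ndarray,
    y: Image2D | np.ndarray,
    data_range: float = 1.0,
    *,
    sigma: float = 1.5,
    global_window: bool = False,
) -> float:
    """Mean structural similarity index.

    Local statistics are taken in Gaussian windows (σ=1.5 px, truncated at
    3.5σ, i.e. 11×11) with the usual stabilisers C1=(0.01·L)² and
    C2=(0.03·L)² for dynamic range L; the mean over the valid interior is
    returned.  ``global_window=True`` instead evaluates the SSIM formula
    once on whole-image statistics.  Raw SSIM lies in (−1, 1]; negative
    values indicate anticorrelated structure.
    """
    xa = np.asarray(x.values if isinstance(x, Image2D) else x, dtype=float)
    ya = np.asarray(y.values if isinstance(y, Image2D) else y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    if global_window:
        mx, my = xa.mean(), ya.mean()
        vx, vy = xa.var(), ya.var()
        cov = ((xa - mx) * (ya - my)).mean()
        return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
    truncate = 3.5
    flt = lambda a: ndimage.gaussian_filter(a, sigma, truncate=truncate, mode="reflect")  # noqa: E731
    mx, my = flt(xa), flt(ya)
    vx = flt(xa * xa) - mx * mx
    vy = flt(ya * ya) - my * my
    cov = flt(xa * ya) - mx * my
    ssim_map = ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    pad = int(truncate * sigma + 0.5)
    if min(ssim_map.shape) > 2 * pad:
        ssim_map = ssim_map[pad:-pad, pad:-pad]
    return float(ssim_map.mean())


def corr(x: Image2D | np.ndarray, y: Image2D | np.ndarray) -> float:
    """Pearson linear correlation over all pixels, in [−1, 1].

    Evaluated literally as the ratio of the sum of multiplied deviations
    to the square root of the product of the summed squared deviations.
    """
    xa = np.asarray(x.values if isinstance(x, Image2D) else x, dtype=float).ravel()
    ya = np.asarray(y.values if isinstance(y, Image2D) else y, dtype=float).ravel()
    if xa.shape != ya.shape:
        raise ValueError("shape mismatch")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation is undefined for a constant image")
    r = float(np.sum(dx * dy)) / float(np.sqrt(sxx * syy))
    return float(np.clip(r, -1.0, 1.0))
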