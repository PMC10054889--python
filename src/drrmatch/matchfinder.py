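"""End-to-end angle search: generate DRRs over a rotation range, register
each against a reference X-ray and select the best-matching projection.

Protocol: for every angle of the ladder ``base ± half_range`` the DRR is
resampled to square pixels, resized onto the common working grid of the
reference image, optionally histogram-matched to the reference, and
registered with demons; SSIM and Pearson correlation between the warped
DRR and the reference are tabulated.  Angles are reported both raw
(canonical [0, 360)) and normalised to (−180, 180] about zero so that a
range such as 345°..15° reads −15°..15°.

The consensus rule mirrors how a surgeon reads the two metric curves:
each metric nominates its argmax; if they agree that angle wins, otherwise
the nominee closer to the base projection (smaller |normalised angle|)
is chosen, with a residual tie going to the higher SSIM.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import CTVolume, Image2D, save_image
from .projection import generate_series, resample_isotropic
from .registration import DemonsParams, demons_register, histogram_match

log = logging.getLogger(__name__)

DEFAULT_WORKING_SIZE = 512


@dataclass
class AngleRow:
    angle_deg: float
    normalized_angle_deg: float
    ssim: float  # clamped at 0 for reporting
    corr: float
    ssim_raw: float = 0.0


@dataclass
class AngleSearchResult:
    table: list[AngleRow]
    best_by_ssim: float
    best_by_corr: float
    consensus_best: float
    histmatch_used: bool
    warped_best: Image2D | None = None
    reference: Image2D | None = None


def normalize_angle(theta_deg: float) -> float:
    """Map an angle into (−180, 180] (e.g. 345 → −15, 540 → 180)."""
    t = float(theta_deg) % 360.0
    if t > 180.0:
        t -= 360.0
    return t


def _normalize01(a: np.ndarray, clip_percentiles: tuple[float, float] | None = (1.0, 99.0)) -> np.ndarray:
    """Percentile-clip then min-max normalise to [0, 1]."""
    a = np.asarray(a, dtype=float)
    if clip_percentiles is not None:
        lo, hi = np.percentile(a, clip_percentiles)
        if hi > lo:
            a = np.clip(a, lo, hi)
    amin, amax = a.min(), a.max()
    if amax <= amin:
        return np.zeros_like(a)
    return (a - amin) / (amax - amin)


def _to_working_grid(img: Image2D, shape: tuple[int, int]) -> Image2D:
    from skimage.transform import resize

    if img.shape == shape:
        return img
    out = resize(img.values, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return Image2D(out)


def prepare_reference(ref: Image2D, working_size: int = DEFAULT_WORKING_SIZE) -> Image2D:
    """Normalise the reference to [0,1] and cap its longest side at ``working_size``."""
    vals = _normalize01(ref.values)
    rows, cols = vals.shape
    longest = max(rows, cols)
    if longest > working_size:
        scale = working_size / longest
        shape = (max(2, int(round(rows * scale))), max(2, int(round(cols * scale))))
        return _to_working_grid(Image2D(vals), shape)
    return Image2D(vals)


def search(
    ref: Image2D,
    vol: CTVolume,
    base_deg: float,
    half_range_deg: float,
    step_deg: float,
    demons: DemonsParams | None = None,
    use_histmatch: bool = False,
    working_size: int = DEFAULT_WORKING_SIZE,
    _register=demons_register,
) -> AngleSearchResult:
    """Register every DRR of the angle ladder to ``ref`` and tabulate metrics."""
    if demons is None:
        demons = DemonsParams()
    ref_w = prepare_reference(ref, working_size)
    series = generate_series(vol, base_deg, half_range_deg, step_deg)
    rows: list[AngleRow] = []
    best_warped: Image2D | None = None
    best_raw = -np.inf
    for drr in series.projections:
        angle = drr.angle_deg
        try:
            iso = resample_isotropic(drr)
            work = _to_working_grid(Image2D(_normalize01(iso.values)), ref_w.shape)
            if use_histmatch:
                work = histogram_match(work, ref_w)
            res = _register(work, ref_w, demons)
        except Exception as exc:  # annotate the failing angle
            raise RuntimeError(f"registration failed at angle {angle:.1f} deg: {exc}") from exc
        raw = res.ssim
        row = AngleRow(angle, normalize_angle(angle), max(0.0, raw), res.corr, ssim_raw=raw)
        if raw < 0.0:
            log.info("angle %.1f: raw SSIM %.4f clamped to 0 for reporting", angle, raw)
        rows.append(row)
        score = max(raw, res.corr)
        if score > best_raw:
            best_raw = score
            best_warped = res.warped
    b_ssim, b_corr, consensus = select_best(rows)
    return AngleSearchResult(
        rows, b_ssim, b_corr, consensus, histmatch_used=use_histmatch, warped_best=best_warped, reference=ref_w
    )


def _argbest(rows: list[AngleRow], key) -> AngleRow:
    # highest metric; ties -> smaller |normalised angle|, then smaller angle
    return max(rows, key=lambda r: (key(r), -abs(r.normalized_angle_deg), -r.angle_deg))


def select_best(rows: list[AngleRow]) -> tuple[float, float, float]:
    """Per-metric argmax plus the consensus angle.

    The consensus is the common argmax when SSIM and correlation agree;
    otherwise the nominee with the smaller |normalised angle| (closest to
    the base projection), a residual tie going to the higher SSIM.
    """
    if not rows:
        raise ValueError("empty metric table")
    r_ssim = _argbest(rows, lambda r: r.ssim)
    r_corr = _argbest(rows, lambda r: r.corr)
    if r_ssim.angle_deg == r_corr.angle_deg:
        consensus = r_ssim.angle_deg
    else:
        a, b = abs(r_ssim.normalized_angle_deg), abs(r_corr.normalized_angle_deg)
        if a < b:
            consensus = r_ssim.angle_deg
        elif b < a:
            consensus = r_corr.angle_deg
        else:
            consensus = r_ssim.angle_deg if r_ssim.ssim >= r_corr.ssim else r_corr.angle_deg
    return r_ssim.angle_deg, r_corr.angle_deg, consensus


def report(result: AngleSearchResult, out: str | Path) -> None:
    """Write the per-angle metric table (CSV), the metric-vs-angle curves and
    reference/warped composite images into ``out``.

    Rendering is deterministic: re-running on the same result produces
    byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "metrics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["angle_deg", "normalized_angle_deg", "ssim", "corr"])
        for r in result.table:
            w.writerow([f"{r.angle_deg:.4f}", f"{r.normalized_angle_deg:.4f}", f"{r.ssim:.6f}", f"{r.corr:.6f}"])

    ang = [r.normalized_angle_deg for r in result.table]
    order = np.argsort(ang)
    ang_s = np.asarray(ang)[order]
    ssim_s = np.asarray([r.ssim for r in result.table])[order]
    corr_s = np.asarray([r.corr for r in result.table])[order]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(ang_s, ssim_s, "o-", label="SSIM", ms=3)
    ax.plot(ang_s, corr_s, "s-", label="CORR", ms=3)
    best_norm = normalize_angle(result.consensus_best)
    ax.axvline(best_norm, color="green", ls="--", label=f"best {best_norm:.0f}°")
    ax.set_xlabel("normalized projection angle (deg)")
    ax.set_ylabel("similarity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "metrics_vs_angle.png", dpi=120, metadata={"Software": None})
    plt.close(fig)

    if result.warped_best is not None and result.reference is not None:
        ref = np.clip(result.reference.values, 0, 1)
        wrp = np.clip(result.warped_best.values, 0, 1)
        blend = 0.5 * ref + 0.5 * wrp
        save_image(Image2D(blend), out / "composite_blend.png")
        rgb = np.stack([ref, wrp, np.zeros_like(ref)], axis=-1)
        import imageio.v2 as iio

        iio.imwrite(out / "composite_rgb.png", (rgb * 255).round().astype(np.uint8))
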