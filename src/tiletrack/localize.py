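"""Second-step registration: locate the tumor on the residual image.

Once the transformed background DRR has been subtracted, the tumor is the
dominant structure left on the projection. Its position is found by
normalized cross-correlation of the tumor-DRR template at every integer
placement inside a search window, optionally refined to sub-pixel
precision by a quadratic fit around the NCC peak. Detector pixels are
converted to millimetres in the isocenter plane through the imaging
geometry (Δmm = Δpx · pitch · SAD/SDD), and per-frame locations are
assembled into trajectories that can be scored against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template as _sk_match_template

from .geometry import ProjectionGeometry, pixels_to_mm
from .images import Image2D, as_image_array
from .preprocess import (
    ClaheParams,
    MarkerConstellation,
    MarkerSet,
    apply_clahe,
    detect_markers,
    locate_constellation,
    remove_markers,
)
from .subtraction import build_map_grid, subtract_background
from .tiles import TileConfig, optimize_tile_shift

__all__ = [
    "TumorLocation",
    "Trajectory",
    "TrackingErrorSummary",
    "TumorTemplate",
    "TrackerConfig",
    "match_template",
    "make_tumor_template",
    "make_residual_template",
    "track_sequence",
    "evaluate_tracking",
    "summarize_tracking",
]


@dataclass
class TumorLocation:
    """Per-frame tumor position estimate."""

    frame: int
    u_px: float
    v_px: float
    x_mm_iso: float
    y_mm_iso: float
    score: float
    window: tuple[int, int, int, int]  # (row0, row1, col0, col1)
    flag: str = "ok"


@dataclass
class Trajectory:
    """Ordered per-frame tumor locations for one (gantry, imager) set."""

    gantry_deg: float
    imager_deg: float
    locations: list[TumorLocation] = field(default_factory=list)
    truth: pd.DataFrame | None = None  # columns u_px, v_px, x_mm_iso, y_mm_iso

    def __post_init__(self) -> None:
        frames = [loc.frame for loc in self.locations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [l.frame for l in self.locations],
                "gantry_deg": self.gantry_deg,
                "imager_deg": self.imager_deg,
                "u_px": [l.u_px for l in self.locations],
                "v_px": [l.v_px for l in self.locations],
                "x_mm_iso": [l.x_mm_iso for l in self.locations],
                "y_mm_iso": [l.y_mm_iso for l in self.locations],
                "ncc_peak": [l.score for l in self.locations],
                "flag": [l.flag for l in self.locations],
            }
        )


@dataclass
class TrackingErrorSummary:
    """Per-angle and overall 2D localization errors (isocenter mm)."""

    per_angle: pd.DataFrame  # gantry_deg, imager_deg, max_mm, mean_mm, n
    overall_max_mm: float
    overall_mean_mm: float

    def __post_init__(self) -> None:
        if self.overall_max_mm < self.overall_mean_mm - 1e-12:
            raise ValueError("max error cannot be below the mean error")


def _quadratic_offset(sm1: float, s0: float, sp1: float) -> float:
    denom = sm1 - 2.0 * s0 + sp1
    if denom >= 0:  # not a proper maximum
        return 0.0
    off = 0.5 * (sm1 - sp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def match_template(
    residual,
    template,
    window: tuple[int, int, int, int] | None = None,
    subpixel: bool = False,
    min_score: float = 0.5,
):
    """NCC template matching inside a window of the residual image.

    Returns ``(row, col, score, flag)`` where (row, col) is the placement
    (top-left) of the best match in full-image coordinates; ties resolve
    to the smallest row-major placement. ``flag`` is "low-confidence" when
    the peak NCC falls below ``min_score``. With ``subpixel`` the peak is
    refined by separable quadratic fits over its 3×3 NCC neighborhood,
    moving it at most 0.5 px per axis.
    """
    img = as_image_array(residual)
    tmpl = np.asarray(template, dtype=float)
    if window is None:
        window = (0, img.shape[0], 0, img.shape[1])
    r0, r1, c0, c1 = window
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r1 - r0 <= tmpl.shape[0] or c1 - c0 <= tmpl.shape[1]:
        raise ValueError("window must be strictly larger than the template")
    sub = img[r0:r1, c0:c1]
    ncc = _sk_match_template(sub, tmpl, pad_input=False)
    pr, pc = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[pr, pc])
    row, col = float(pr), float(pc)
    if subpixel:
        if 0 < pr < ncc.shape[0] - 1:
            row += _quadratic_offset(ncc[pr - 1, pc], ncc[pr, pc], ncc[pr + 1, pc])
        if 0 < pc < ncc.shape[1] - 1:
            col += _quadratic_offset(ncc[pr, pc - 1], ncc[pr, pc], ncc[pr, pc + 1])
    flag = "ok" if score >= min_score else "low-confidence"
    return row + r0, col + c0, score, flag


@dataclass
class TumorTemplate:
    """Tumor-DRR template with the tumor center's position in template
    coordinates, so a matched placement converts to a center estimate."""

    data: np.ndarray
    center_row: float  # v of the tumor center within the template
    center_col: float  # u of the tumor center within the template


def make_tumor_template(
    tumor_drr, tumor_center_px: tuple[float, float], margin_px: int = 3, threshold: float = 1e-6
) -> TumorTemplate:
    """Crop the tumor DRR to its support (plus margin) and record where the
    projected tumor center sits inside the crop.

    ``tumor_center_px`` is (u_px, v_px) of the static tumor center on the
    detector (from the projection geometry).
    """
    img = as_image_array(tumor_drr)
    nz = np.nonzero(np.abs(img) > threshold * max(np.abs(img).max(), 1e-300))
    if len(nz[0]) == 0:
        raise ValueError("tumor DRR has no support")
    r0 = max(int(nz[0].min()) - margin_px, 0)
    r1 = min(int(nz[0].max()) + margin_px + 1, img.shape[0])
    c0 = max(int(nz[1].min()) - margin_px, 0)
    c1 = min(int(nz[1].max()) + margin_px + 1, img.shape[1])
    u_px, v_px = tumor_center_px
    return TumorTemplate(
        data=img[r0:r1, c0:c1].copy(),
        center_row=v_px - r0,
        center_col=u_px - c0,
    )


def make_residual_template(
    background_drr,
    tumor_drr,
    tumor_center_px: tuple[float, float],
    clahe: ClaheParams | None = None,
    margin_px: int = 3,
) -> TumorTemplate:
    """Tumor template in the residual-image domain, from planning data only.

    The residual the second registration searches is formed from CLAHE'd
    images, so the tumor's appearance there is its attenuation footprint
    modulated by the local slope of the equalization mapping — not the raw
    line integral. This template reproduces that appearance by CLAHE'ing
    the composite (background + tumor) DRR and the background DRR and
    taking their difference over the tumor's support box. Matching it
    reduces the bias that strong background edges (heart, ribs) under the
    tumor otherwise induce on the NCC peak.
    """
    bg = as_image_array(background_drr)
    td = as_image_array(tumor_drr)
    if bg.shape != td.shape:
        raise ValueError("background and tumor DRRs must share the detector grid")
    pitch = (
        background_drr.pixel_pitch_mm if isinstance(background_drr, Image2D) else 1.0
    )
    eq_comp = apply_clahe(Image2D(bg + td, pitch), clahe).data
    eq_bg = apply_clahe(Image2D(bg, pitch), clahe).data
    diff = eq_comp - eq_bg
    nz = np.nonzero(td > 1e-6 * max(td.max(), 1e-300))
    if len(nz[0]) == 0:
        raise ValueError("tumor DRR has no support")
    r0 = max(int(nz[0].min()) - margin_px, 0)
    r1 = min(int(nz[0].max()) + margin_px + 1, td.shape[0])
    c0 = max(int(nz[1].min()) - margin_px, 0)
    c1 = min(int(nz[1].max()) + margin_px + 1, td.shape[1])
    u_px, v_px = tumor_center_px
    return TumorTemplate(
        data=diff[r0:r1, c0:c1].copy(),
        center_row=v_px - r0,
        center_col=u_px - c0,
    )


@dataclass
class TrackerConfig:
    """Configuration of the per-frame two-step matching pipeline."""

    base_tiles: TileConfig
    clahe: ClaheParams = field(default_factory=ClaheParams)
    search_range_px: int | None = None
    search_step_px: int | None = None
    window_halfwidth_factor: float = 0.75  # × tile size, around previous location
    subpixel: bool = False
    min_score: float = 0.5
    marker_template: np.ndarray | None = None
    marker_count: int = 0
    marker_inpaint_radius_px: float | None = None
    marker_min_score: float = 0.45
    # Detect markers on a high-pass copy (image minus a Gaussian blur of
    # this sigma): markers are small-scale and survive, while smooth
    # large-scale anatomy that confounds the blob template is flattened.
    marker_highpass_sigma: float | None = None
    # Minimum separation of detections; implanted markers can sit closer
    # than a full template footprint in projection.
    marker_min_separation_px: int | None = None
    # Preferred marker-removal path: match all markers jointly as a rigid
    # constellation anchored to the tumor position (robust against rib and
    # chest-wall edge false peaks). Overrides the per-marker detection.
    marker_constellation: MarkerConstellation | None = None


def _detector_offset_mm(u_px, v_px, geometry: ProjectionGeometry):
    vc, uc = geometry.detector_center_px()
    x = float(pixels_to_mm(u_px - uc, geometry))
    y = float(pixels_to_mm(v_px - vc, geometry))
    return x, y


def track_sequence(
    frames,
    background_drr,
    tumor_template: TumorTemplate,
    geometry: ProjectionGeometry,
    config: TrackerConfig,
) -> Trajectory:
    """Run the full two-step matching on a sequence of projections.

    Per frame: marker removal (if configured) → CLAHE → tile-shift NCC
    registration against the CLAHE'd background DRR → per-tile linear
    intensity transform and background subtraction → tumor-template NCC on
    the residual. The first frame searches the bad tile expanded by half a
    tile on each side; later frames search a window centered on the
    previous location. A failed stage flags the frame (carrying the
    previous location forward) and the trajectory continues.
    """
    bg_eq = apply_clahe(background_drr, config.clahe)
    tmpl = tumor_template.data
    th, tw = tmpl.shape
    traj = Trajectory(gantry_deg=geometry.gantry_deg, imager_deg=geometry.imager_deg)
    prev_center: tuple[float, float] | None = None  # (row, col)
    half_w = int(
        config.window_halfwidth_factor
        * max(config.base_tiles.tile_width, config.base_tiles.tile_height)
    )

    def locate(P: np.ndarray, prev: tuple[float, float] | None):
        """One pass of CLAHE → tile registration → subtraction → matching."""
        P_eq = apply_clahe(Image2D(P, geometry.pixel_pitch_mm), config.clahe)
        match = optimize_tile_shift(
            P_eq, bg_eq, config.base_tiles,
            search_range_px=config.search_range_px,
            step_px=config.search_step_px,
        )
        grid = build_map_grid(P_eq, bg_eq, match)
        residual = subtract_background(P_eq, bg_eq, grid)
        cfg = match.config
        if prev is None:
            bu, bv = match.bad_tile
            rs, cs = cfg.proj_tile_slices(bu, bv)
            window = (
                rs.start - cfg.tile_height // 2,
                rs.stop + cfg.tile_height // 2,
                cs.start - cfg.tile_width // 2,
                cs.stop + cfg.tile_width // 2,
            )
        else:
            pr, pc = prev
            window = (
                int(pr - tumor_template.center_row) - half_w,
                int(pr - tumor_template.center_row) + th + half_w,
                int(pc - tumor_template.center_col) - half_w,
                int(pc - tumor_template.center_col) + tw + half_w,
            )
        row, col, score, flag = match_template(
            residual, tmpl, window=window,
            subpixel=config.subpixel, min_score=config.min_score,
        )
        # The windows are heuristic; a peak pinned to the window border or
        # a low-confidence score means the true optimum may lie outside,
        # so re-match over the whole residual.
        r0, r1, c0, c1 = window
        on_border = (
            row <= max(r0, 0) + 0.5
            or col <= max(c0, 0) + 0.5
            or row >= min(r1, residual.shape[0]) - th - 0.5
            or col >= min(c1, residual.shape[1]) - tw - 0.5
        )
        if on_border or flag == "low-confidence":
            row, col, score, flag = match_template(
                residual, tmpl, window=None,
                subpixel=config.subpixel, min_score=config.min_score,
            )
        return row, col, score, flag, window

    for k, frame in enumerate(frames):
        try:
            P = as_image_array(frame)
            if config.marker_constellation is not None:
                # The constellation search is anchored on the tumor: use
                # the previous location, or a provisional first-pass
                # localization with the markers still in place.
                if prev_center is not None:
                    prior = prev_center
                else:
                    prow, pcol, _, _, _ = locate(P, None)
                    prior = (
                        prow + tumor_template.center_row,
                        pcol + tumor_template.center_col,
                    )
                markers = locate_constellation(P, config.marker_constellation, prior)
                P = remove_markers(P, markers).data
            elif config.marker_count > 0 and config.marker_template is not None:
                det_img = P
                if config.marker_highpass_sigma is not None:
                    det_img = P - gaussian_filter(P, config.marker_highpass_sigma)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # fewer markers than expected is fine
                    markers = detect_markers(
                        det_img,
                        config.marker_template,
                        config.marker_count,
                        min_score=config.marker_min_score,
                        min_separation_px=config.marker_min_separation_px,
                    )
                if config.marker_inpaint_radius_px is not None:
                    markers = MarkerSet(
                        centers=markers.centers,
                        radius_px=config.marker_inpaint_radius_px,
                        scores=markers.scores,
                    )
                P = remove_markers(P, markers).data
            row, col, score, flag, window = locate(P, prev_center)
            v_px = row + tumor_template.center_row
            u_px = col + tumor_template.center_col
            x_mm, y_mm = _detector_offset_mm(u_px, v_px, geometry)
            traj.locations.append(
                TumorLocation(k, u_px, v_px, x_mm, y_mm, score, window, flag)
            )
            prev_center = (v_px, u_px)
        except Exception:
            if prev_center is not None:
                v_px, u_px = prev_center
                x_mm, y_mm = _detector_offset_mm(u_px, v_px, geometry)
            else:
                u_px = v_px = x_mm = y_mm = float("nan")
            traj.locations.append(
                TumorLocation(k, u_px, v_px, x_mm, y_mm, float("nan"), (0, 0, 0, 0), "failed")
            )
    return traj


def _frame_errors(traj: Trajectory, truth: pd.DataFrame) -> np.ndarray:
    est = traj.to_dataframe()
    if len(est) != len(truth):
        raise ValueError("trajectory and truth differ in length")
    dx = est["x_mm_iso"].to_numpy() - truth["x_mm_iso"].to_numpy()
    dy = est["y_mm_iso"].to_numpy() - truth["y_mm_iso"].to_numpy()
    return np.hypot(dx, dy)


def evaluate_tracking(traj: Trajectory, truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-frame 2D Euclidean error (isocenter mm) against ground truth."""
    if truth is None:
        truth = traj.truth
    if truth is None:
        raise ValueError("no ground truth available for this trajectory")
    err = _frame_errors(traj, truth)
    out = traj.to_dataframe()
    out["error_mm"] = err
    return out


def summarize_tracking(trajectories: list[Trajectory]) -> TrackingErrorSummary:
    """Per-angle maximum/average errors and the pooled overall figures."""
    rows = []
    all_err: list[np.ndarray] = []
    for traj in trajectories:
        err = _frame_errors(traj, traj.truth)
        all_err.append(err)
        rows.append(
            {
                "gantry_deg": traj.gantry_deg,
                "imager_deg": traj.imager_deg,
                "max_mm": float(err.max()),
                "mean_mm": float(err.mean()),
                "n_frames": len(err),
            }
        )
    pooled = np.concatenate(all_err)
    return TrackingErrorSummary(
        per_angle=pd.DataFrame(rows),
        overall_max_mm=float(pooled.max()),
        overall_mean_mm=float(pooled.mean()),
    )
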