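"""Semi-automatic landmark tracking by normalized cross-correlation.

The user annotates a point in frame 0 (LV end-diastole).  A small square
template (the "mask") centred on that point is matched by normalized
cross-correlation against a search region in the next frame; the correlation
peak is the new position, the mask is re-extracted there (adaptive mode), and
the procedure repeats for every frame of the cardiac cycle.  The only user
input is the initial annotation.

Positions are 0-based ``(row, col)``, integer-valued unless subpixel
refinement is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import FlatTextureError, TrackingError, ValidationError
from .io import CineSeries, LandmarkSet

FLAG_LOW_CORRELATION = "low_correlation"
FLAG_CLAMPED = "clamped_to_border"


@dataclass
class TrackerConfig:
    """Tuning knobs of the template tracker.

    ``template_half_width`` h gives a (2h+1)² mask — the default 5 px spans
    ~14 mm at the typical 1.25 mm spacing, enough to cover wall texture.
    ``search_half_width`` bounds the per-frame excursion (10 px = 12.5 mm,
    generous for annular motion at 30-40 frames/cycle).  ``adaptive_template``
    re-extracts the mask from each newly matched frame (the default
    behaviour); disable it to quantify drift with a fixed frame-0 mask.
    ``subpixel`` turns on separable 3-point parabolic peak refinement,
    capped at ±0.5 px per axis.

    Chaining frame-to-frame matches lets small per-step errors accumulate as
    drift.  With ``drift_correction`` (on by default) each adaptive match is
    re-anchored against the frame-0 mask in a small neighbourhood of the
    candidate position; the correction is accepted only when that match
    correlates at least at ``min_correlation`` and moves the point by no
    more than 2 px, so it engages when the tissue still resembles its
    end-diastolic appearance and falls back to the pure mask update when it
    does not.
    """

    template_half_width: int = 5
    search_half_width: int = 10
    subpixel: bool = False
    adaptive_template: bool = True
    drift_correction: bool = True
    min_correlation: float = 0.5

    #: maximum accepted drift-correction step, px
    max_drift_correction_px: float = 2.0

    def __post_init__(self) -> None:
        if self.template_half_width < 2:
            raise ValidationError("template_half_width must be >= 2")
        if self.search_half_width < self.template_half_width:
            raise ValidationError("search_half_width must be >= template_half_width")
        if not -1.0 <= self.min_correlation <= 1.0:
            raise ValidationError("min_correlation must lie in [-1, 1]")


@dataclass
class Trajectory:
    """Per-frame position, match score and QC flags of one tracked landmark."""

    positions: np.ndarray  # (T, 2) float (row, col)
    scores: np.ndarray  # (T,) correlation coefficients; scores[0] = 1
    flags: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.positions.shape != (len(self.scores), 2):
            raise ValidationError("positions must be (T, 2) matching scores length")
        if not self.flags:
            self.flags = [set() for _ in range(len(self.scores))]

    @property
    def n_frames(self) -> int:
        return len(self.scores)

    @property
    def flagged_fraction(self) -> float:
        return sum(bool(f) for f in self.flags) / self.n_frames

    def to_csv(self, path) -> None:
        """Write ``frame,row,col,score,flags`` rows (flags '|'-joined)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "row": self.positions[:, 0],
                "col": self.positions[:, 1],
                "score": self.scores,
                "flags": ["|".join(sorted(f)) for f in self.flags],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(Path(path), keep_default_na=False)
        flags = [set(s.split("|")) - {""} for s in df["flags"].astype(str)]
        return cls(
            positions=np.column_stack([df["row"].to_numpy(), df["col"].to_numpy()]),
            scores=df["score"].to_numpy(),
            flags=flags,
        )


def ncc_map(template: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``template`` at every offset in ``region``.

    The value at offset ``(i, j)`` is the Pearson correlation between the
    template and the equally sized region window starting at ``(i, j)``; the
    output shape is ``region.shape - template.shape + 1``.  Windows with zero
    intensity variance get correlation 0.

    Raises
    ------
    FlatTextureError
        If the template itself has zero variance.
    """
    template = np.asarray(template, dtype=np.float64)
    region = np.asarray(region, dtype=np.float64)
    if template.ndim != 2 or region.ndim != 2:
        raise ValidationError("template and region must be 2D")
    if region.shape[0] < template.shape[0] or region.shape[1] < template.shape[1]:
        raise ValidationError(
            f"region {region.shape} must not be smaller than template {template.shape}"
        )

    tzm = template - template.mean()
    t_ss = float(np.sum(tzm * tzm))
    scale = max(1.0, float(np.abs(template).max(initial=0.0)))
    if t_ss <= template.size * (1e-14 * scale) ** 2:
        raise FlatTextureError("template has (near-)zero intensity variance")

    windows = sliding_window_view(region, template.shape)
    n = template.size
    wsum = windows.sum(axis=(-2, -1))
    cross = np.einsum("ijkl,kl->ij", windows, tzm)  # == sum((w - wmean) * tzm)
    w_ss = np.einsum("ijkl,ijkl->ij", windows, windows) - wsum * wsum / n
    w_ss = np.clip(w_ss, 0.0, None)

    rscale = max(1.0, float(np.abs(region).max(initial=0.0)))
    flat = w_ss <= n * (1e-12 * rscale) ** 2
    denom = np.sqrt(t_ss * np.where(flat, 1.0, w_ss))
    out = np.where(flat, 0.0, cross / denom)
    return np.clip(out, -1.0, 1.0)


def _extract(img: np.ndarray, center: np.ndarray, half: int) -> np.ndarray:
    r, c = int(center[0]), int(center[1])
    return img[r - half : r + half + 1, c - half : c + half + 1]


def _extract_subpixel(img: np.ndarray, center: np.ndarray, half: int) -> np.ndarray:
    """Bilinear template sampled on a grid centred exactly at ``center``.

    Keeping the mask centre at the (fractional) previous position prevents
    the re-centring phase error that otherwise accumulates as drift when
    subpixel displacements are chained frame to frame.
    """
    from scipy import ndimage

    offs = np.arange(-half, half + 1, dtype=float)
    rows = center[0] + offs
    cols = center[1] + offs
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(np.asarray(img, float), grid, order=1, mode="nearest")


def _parabolic_offset(m: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Separable 3-point parabolic refinement around the integer peak, ±0.5 px."""

    def axis_offset(lo: float, mid: float, hi: float) -> float:
        denom = lo - 2.0 * mid + hi
        if denom >= 0.0:  # not a proper maximum; keep the integer peak
            return 0.0
        return float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < i < m.shape[0] - 1:
        dr = axis_offset(m[i - 1, j], m[i, j], m[i + 1, j])
    if 0 < j < m.shape[1] - 1:
        dc = axis_offset(m[i, j - 1], m[i, j], m[i, j + 1])
    return dr, dc


def _best_peak(m: np.ndarray, center_rc: tuple[float, float], origin: tuple[int, int],
               half: int) -> tuple[int, int]:
    """Integer argmax with deterministic tie-breaking.

    Ties within 1e-12 of the maximum are resolved toward the window centre
    closest (Euclidean) to ``center_rc`` (the previous position), remaining
    ties in row-major order.
    """
    peak = float(m.max())
    cand = np.argwhere(m >= peak - 1e-12)
    if len(cand) == 1:
        return int(cand[0, 0]), int(cand[0, 1])
    centers = cand + np.array([origin[0] + half, origin[1] + half])
    d2 = ((centers - np.asarray(center_rc)) ** 2).sum(axis=1)
    # argwhere is row-major, so the first minimum settles residual ties
    k = int(np.argmin(d2))
    return int(cand[k, 0]), int(cand[k, 1])


def track_point(series: CineSeries, start: tuple[float, float],
                config: TrackerConfig | None = None) -> Trajectory:
    """Track one landmark through all frames of a cine series.

    The search region in frame ``t`` is centred on the position found at
    ``t-1``; with ``adaptive_template`` the mask is re-extracted around each
    new match (mask update), otherwise the frame-0 mask is matched throughout.
    Border-clipped searches clamp the position and set the
    ``clamped_to_border`` flag rather than raising.
    """
    config = config or TrackerConfig()
    h = config.template_half_width
    s = config.search_half_width
    height, width = series.image_shape
    t_frames = series.n_frames

    start = np.asarray(start, dtype=float)
    if not (h <= start[0] <= height - 1 - h and h <= start[1] <= width - 1 - h):
        raise ValidationError(
            f"start {tuple(start)} violates the {h}-px template margin"
        )

    positions = np.zeros((t_frames, 2))
    scores = np.ones(t_frames)
    flags: list[set[str]] = [set() for _ in range(t_frames)]
    positions[0] = start

    anchor0 = np.clip(np.rint(start), h, [height - 1 - h, width - 1 - h]).astype(int)
    if config.subpixel:
        template0 = _extract_subpixel(series.frames[0], start, h)
        center0 = start.copy()
    else:
        template0 = np.array(_extract(series.frames[0], anchor0, h), dtype=float)
        center0 = anchor0.astype(float)

    def match(template: np.ndarray, frame: np.ndarray, anchor: np.ndarray,
              half_search: int, ref: np.ndarray, t: int):
        """Best template position in ``frame`` near ``anchor``; ties break toward ``ref``."""
        r0 = max(0, anchor[0] - half_search)
        r1 = min(height, anchor[0] + half_search + 1)
        c0 = max(0, anchor[1] - half_search)
        c1 = min(width, anchor[1] + half_search + 1)
        clipped = (r1 - r0 != 2 * half_search + 1) or (c1 - c0 != 2 * half_search + 1)
        try:
            m = ncc_map(template, frame[r0:r1, c0:c1])
        except FlatTextureError as exc:
            raise TrackingError(f"frame {t}: {exc}") from exc
        if not np.any(m != 0.0):
            raise TrackingError(
                f"frame {t}: search region is textureless; tracking aborted"
            )
        i, j = _best_peak(m, tuple(ref), (r0, c0), h)
        dr = dc = 0.0
        if config.subpixel:
            dr, dc = _parabolic_offset(m, i, j)
        center = np.array([r0 + i + h + dr, c0 + j + h + dc])
        return center, float(m[i, j]), clipped

    for t in range(1, t_frames):
        prev = positions[t - 1]
        anchor = np.clip(np.rint(prev), h, [height - 1 - h, width - 1 - h]).astype(int)
        if config.adaptive_template:
            if config.subpixel:
                template = _extract_subpixel(series.frames[t - 1], prev, h)
                src_center = prev
            else:
                template = _extract(series.frames[t - 1], anchor, h)
                src_center = anchor.astype(float)
            base = prev  # displacement is added to the (possibly fractional) position
        else:
            template = template0
            base = start
            src_center = center0

        match_center, score, clipped = match(
            template, series.frames[t], anchor, s, prev, t
        )
        new = base + (match_center - src_center)

        if config.adaptive_template and config.drift_correction:
            # re-anchor against the end-diastolic mask near the candidate
            anchor_c = np.clip(np.rint(new), h, [height - 1 - h, width - 1 - h]).astype(int)
            center_c, score_c, _ = match(
                template0, series.frames[t], anchor_c, h + 3, new, t
            )
            corrected = start + (center_c - center0)
            if (score_c >= config.min_correlation
                    and np.linalg.norm(corrected - new) <= config.max_drift_correction_px):
                new = corrected
                score = score_c

        clamped_new = np.clip(new, h, [height - 1 - h, width - 1 - h])
        if clipped or not np.array_equal(new, clamped_new):
            flags[t].add(FLAG_CLAMPED)
        if score < config.min_correlation:
            flags[t].add(FLAG_LOW_CORRELATION)

        positions[t] = clamped_new
        scores[t] = score
        if not config.subpixel:
            positions[t] = np.rint(positions[t])

    return Trajectory(positions=positions, scores=scores, flags=flags)


def track_landmarks(series: CineSeries, landmarks: LandmarkSet,
                    config: TrackerConfig | None = None) -> dict[str, Trajectory]:
    """Track the three annotated landmarks independently; keys are landmark names."""
    config = config or TrackerConfig()
    if landmarks.view != series.view:
        raise ValidationError(
            f"landmark view {landmarks.view} does not match series view {series.view}"
        )
    landmarks.validate_bounds(series.image_shape, config.template_half_width)
    out: dict[str, Trajectory] = {}
    for name, point in landmarks.points.items():
        try:
            out[name] = track_point(series, point, config)
        except TrackingError as exc:
            raise TrackingError(f"{name}: {exc}") from exc
    return out
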