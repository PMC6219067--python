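"""Synthetic cine phantom with prescribed triphasic LA deformation.

The phantom emulates what the tracker actually sees on a long-axis cine: two
fixed atrioventricular junction points and a mid-posterior LA point whose
distances to the junctions follow a prescribed triphasic strain programme —
rise to the reservoir peak during ventricular systole, fall to the diastolic
plateau (conduit emptying), hold through diastasis, and return to zero with
the atrial kick.  Each landmark carries a rigid patch of smooth random
texture over a static textured background, plus optional additive Gaussian
noise, so normalized cross-correlation has something to lock onto and the
ground-truth trajectory of every landmark is known exactly.

Geometry: the two junctions are fixed; the posterior point is placed each
frame at the intersection of two circles centred on the junctions with radii
D0_wall * (1 + eps_wall(t)/100).  This makes per-wall distance programmes
exact to machine precision and permits distinct amplitudes per wall.

Defaults mirror a typical acquisition (30 frames/cycle, 1.25 x 1.25 mm
spacing, ~1 s RR interval) and a normal-control deformation pattern
(reservoir strain 35.3 %, booster strain 17.2 %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MonophasicCurveError, ValidationError
from .io import CineSeries, LandmarkSet
from .strain import (
    PhasicStrainResult,
    PhaseTimes,
    StrainCurve,
    detect_phases,
    phasic_parameters,
    strain_rate_curve,
)


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic cine.

    ``eps_s`` / ``eps_a`` are (wall_a, wall_b) reservoir and booster strain
    amplitudes in percent; ``d0_mm`` the matching end-diastolic
    junction-posterior distances.  Phase fractions place LV end-systole and
    the diastolic plateau within the cycle.  ``noise_sigma`` is the additive
    Gaussian noise SD as a fraction of the intensity range.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 30
    pixel_spacing: tuple[float, float] = (1.25, 1.25)
    frame_interval_ms: float | None = None  # default: 1000 ms RR / n_frames
    view: str = "CH4"
    junction_a: tuple[int, int] = (96, 44)
    junction_b: tuple[int, int] = (96, 84)
    d0_mm: tuple[float, float] = (60.0, 60.0)
    eps_s: tuple[float, float] = (35.3, 35.3)
    eps_a: tuple[float, float] = (17.2, 17.2)
    f_es: float = 0.40
    f_plateau_start: float = 0.60
    f_preA: float = 0.75
    texture_corr_len: float = 3.0
    patch_half_width: int = 10
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValidationError("phantom needs at least 10 frames")
        if not 0.0 < self.f_es < self.f_plateau_start <= self.f_preA < 1.0:
            raise ValidationError(
                "phase fractions must satisfy 0 < f_es < f_plateau_start <= f_preA < 1"
            )
        for es, a in zip(self.eps_s, self.eps_a):
            if not es >= a >= 0.0:
                raise ValidationError("amplitudes must satisfy eps_s >= eps_a >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if self.frame_interval_ms is None:
            self.frame_interval_ms = 1000.0 / self.n_frames

    @property
    def wall_names(self) -> tuple[str, str]:
        from .io import WALL_NAMES

        walls = WALL_NAMES[self.view]
        return walls["junction_a"], walls["junction_b"]


@dataclass
class PhantomGroundTruth:
    """Everything the phantom knows: curves, trajectories, phases, parameters."""

    epsilon: dict[str, np.ndarray]  # wall -> prescribed strain, %
    distance_mm: dict[str, np.ndarray]  # wall -> exact D(t), mm
    trajectories: dict[str, np.ndarray]  # landmark name -> (T, 2) px
    phases: dict[str, PhaseTimes]  # wall -> phases on the clean curve
    params: dict[str, PhasicStrainResult]  # wall -> clean-curve parameters
    walls: tuple[str, str] = ("", "")


def prescribed_strain(n_frames: int, eps_s: float, eps_a: float, f_es: float,
                      f_plateau_start: float, f_preA: float) -> np.ndarray:
    """Piecewise-C1 triphasic strain curve on the frame grid, in percent.

    Cosine smoothsteps: 0 -> eps_s on [0, f_es], eps_s -> eps_a on
    [f_es, f_plateau_start], constant eps_a through [f_plateau_start, f_preA],
    eps_a -> 0 on [f_preA, 1] (cyclic: eps(T) = eps(0) = 0).
    """
    u = np.arange(n_frames) / n_frames
    eps = np.empty(n_frames)
    rise = u <= f_es
    eps[rise] = eps_s * 0.5 * (1.0 - np.cos(np.pi * u[rise] / f_es))
    fall = (u > f_es) & (u <= f_plateau_start)
    eps[fall] = eps_a + (eps_s - eps_a) * 0.5 * (
        1.0 + np.cos(np.pi * (u[fall] - f_es) / (f_plateau_start - f_es))
    )
    plateau = (u > f_plateau_start) & (u <= f_preA)
    eps[plateau] = eps_a
    decay = u > f_preA
    eps[decay] = eps_a * 0.5 * (1.0 + np.cos(np.pi * (u[decay] - f_preA) / (1.0 - f_preA)))
    return eps


def _posterior_path(config: PhantomConfig, eps_a_curve: np.ndarray,
                    eps_b_curve: np.ndarray) -> np.ndarray:
    """Per-frame posterior position (px) from the two distance programmes.

    Intersection of circles centred on the junctions (in mm coordinates);
    of the two solutions the one on the atrial side (smaller row) is taken.
    """
    row_mm, col_mm = config.pixel_spacing
    pa = np.array([config.junction_a[0] * row_mm, config.junction_a[1] * col_mm])
    pb = np.array([config.junction_b[0] * row_mm, config.junction_b[1] * col_mm])
    d_ab = float(np.linalg.norm(pb - pa))
    if d_ab == 0:
        raise ValidationError("junction points must be distinct")
    da = config.d0_mm[0] * (1.0 + eps_a_curve / 100.0)
    db = config.d0_mm[1] * (1.0 + eps_b_curve / 100.0)

    a = (da**2 - db**2 + d_ab**2) / (2.0 * d_ab)
    h_sq = da**2 - a**2
    if np.any(h_sq <= 0):
        raise ValidationError(
            "distance programme has no two-circle intersection; "
            "check d0_mm against the junction separation"
        )
    h = np.sqrt(h_sq)
    unit = (pb - pa) / d_ab
    perp = np.array([-unit[1], unit[0]])  # rotate +90 deg in (row, col)
    base = pa[None, :] + a[:, None] * unit[None, :]
    p1 = base + h[:, None] * perp[None, :]
    p2 = base - h[:, None] * perp[None, :]
    path_mm = p1 if p1[0, 0] < p2[0, 0] else p2  # atrial side: smaller row
    return path_mm / np.array([row_mm, col_mm])


def _smooth_texture(rng: np.random.Generator, shape: tuple[int, int],
                    corr_len: float) -> np.ndarray:
    """Seeded Gaussian noise blurred to the given correlation length, in [0, 1].

    The blur uses periodic boundaries, which keeps the field band-limited so
    subpixel translation by Fourier shift is exact (no resampling blur).
    """
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len, mode="wrap")
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _fourier_shift(tex: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Exact periodic subpixel translation of a band-limited patch."""
    shifted = np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(tex), frac))
    return np.real(shifted)


_PAD = 2  # canvas margin so the shifted window support never truncates
_TAPER = 4  # cosine-taper width (px) of the flat-top blending window


def _shifted_tukey(canvas: int, support: int, frac: float) -> np.ndarray:
    """Flat-top (Tukey) window of width ``support``, shifted by frac.

    Flat at 1 in the interior with a ``_TAPER``-px cosine roll-off at each
    edge: the tracker's template region then observes pure patch texture,
    while the roll-off blends seamlessly into the background.
    """
    i = np.arange(canvas) - _PAD - frac
    d = np.minimum(i, support - 1 - i)
    w = np.where(d >= _TAPER, 1.0, 0.5 - 0.5 * np.cos(np.pi * np.clip(d, 0, _TAPER) / _TAPER))
    w[(i < 0) | (i > support - 1)] = 0.0
    return w


def _render(background: np.ndarray, patches: dict[str, np.ndarray],
            positions: dict[str, np.ndarray],
            n_frames: int, patch_half: int, rng: np.random.Generator,
            noise_sigma: float) -> np.ndarray:
    """Composite rigid textured patches over the background, frame by frame.

    Each patch is translated by the fractional part of its position with an
    exact Fourier shift, and blended with an analytically shifted Hann
    window, so its appearance is strictly invariant under the motion.
    """
    height, width = background.shape
    support = 2 * patch_half + 1
    half = patch_half + _PAD  # canvas half-width, includes the shift margin
    frames = np.empty((n_frames, height, width), dtype=np.float64)
    for t in range(n_frames):
        img = background.copy()
        for name, tex in patches.items():
            p = positions[name][t]
            base = np.floor(p).astype(int)
            frac = p - base
            if not (half <= base[0] < height - half - 1
                    and half <= base[1] < width - half - 1):
                raise ValidationError(
                    f"{name} leaves the image at frame {t}; shrink the deformation"
                )
            w = np.outer(_shifted_tukey(tex.shape[0], support, frac[0]),
                         _shifted_tukey(tex.shape[1], support, frac[1]))
            tx = _fourier_shift(tex, frac)
            sl = (slice(base[0] - half, base[0] + half + 1),
                  slice(base[1] - half, base[1] + half + 1))
            img[sl] = img[sl] * (1.0 - w) + tx * w
        if noise_sigma > 0:
            img = img + rng.standard_normal((height, width)) * noise_sigma
        frames[t] = img
    return frames.astype(np.float32)


def generate_phantom(config: PhantomConfig | None = None
                     ) -> tuple[CineSeries, LandmarkSet, PhantomGroundTruth]:
    """Render the phantom cine and return it with annotations and ground truth.

    Identical config and seed give bit-identical output; distinct seeds
    change the texture and noise but not the ground truth.
    """
    config = config or PhantomConfig()
    t_frames = config.n_frames
    wall_a, wall_b = config.wall_names

    eps = {
        wall_a: prescribed_strain(t_frames, config.eps_s[0], config.eps_a[0],
                                  config.f_es, config.f_plateau_start, config.f_preA),
        wall_b: prescribed_strain(t_frames, config.eps_s[1], config.eps_a[1],
                                  config.f_es, config.f_plateau_start, config.f_preA),
    }
    post_path = _posterior_path(config, eps[wall_a], eps[wall_b])
    trajectories = {
        "junction_a": np.tile(np.asarray(config.junction_a, float), (t_frames, 1)),
        "junction_b": np.tile(np.asarray(config.junction_b, float), (t_frames, 1)),
        "mid_posterior": post_path,
    }
    distance = {
        wall_a: config.d0_mm[0] * (1.0 + eps[wall_a] / 100.0),
        wall_b: config.d0_mm[1] * (1.0 + eps[wall_b] / 100.0),
    }

    # phases and parameters as read off the clean prescribed curves;
    # undefined (and left out) for degenerate flat prescriptions
    phases: dict[str, PhaseTimes] = {}
    params: dict[str, PhasicStrainResult] = {}
    for wall in (wall_a, wall_b):
        curve = StrainCurve(wall=wall, epsilon=eps[wall])
        sr = strain_rate_curve(curve, config.frame_interval_ms)
        try:
            ph = detect_phases(curve, sr)
        except MonophasicCurveError:
            continue
        phases[wall] = ph
        params[wall] = phasic_parameters(curve, sr, ph)

    rng = np.random.default_rng(config.seed)
    background = 0.35 * _smooth_texture(
        rng, (config.height, config.width), config.texture_corr_len
    )
    p = config.patch_half_width
    canvas = 2 * (p + _PAD) + 1
    patches = {
        name: _smooth_texture(rng, (canvas, canvas), config.texture_corr_len)
        for name in trajectories
    }
    frames = _render(background, patches, trajectories, t_frames, p,
                     rng, config.noise_sigma)

    series = CineSeries(
        frames=frames,
        pixel_spacing=config.pixel_spacing,
        frame_interval_ms=config.frame_interval_ms,
        view=config.view,
        subject_id=f"phantom-{config.seed}",
    )
    landmarks = LandmarkSet(
        view=config.view,
        points={name: tuple(traj[0]) for name, traj in trajectories.items()},
    )
    truth = PhantomGroundTruth(
        epsilon=eps, distance_mm=distance, trajectories=trajectories,
        phases=phases, params=params, walls=(wall_a, wall_b),
    )
    return series, landmarks, truth


def textured_motion_series(path_px: np.ndarray, *, height: int = 96, width: int = 96,
                           pixel_spacing: tuple[float, float] = (1.25, 1.25),
                           frame_interval_ms: float = 33.0,
                           patch_half_width: int = 10, texture_corr_len: float = 3.0,
                           noise_sigma: float = 0.0, seed: int = 0) -> CineSeries:
    """A single textured patch following an arbitrary (T, 2) pixel path.

    Convenience builder for tracker validation: the returned series contains
    one rigid patch whose ground-truth position per frame is ``path_px``.
    """
    path_px = np.asarray(path_px, dtype=float)
    if path_px.ndim != 2 or path_px.shape[1] != 2:
        raise ValidationError("path must be (T, 2)")
    rng = np.random.default_rng(seed)
    background = 0.35 * _smooth_texture(rng, (height, width), texture_corr_len)
    p = patch_half_width
    canvas = 2 * (p + _PAD) + 1
    patches = {"blob": _smooth_texture(rng, (canvas, canvas), texture_corr_len)}
    frames = _render(background, patches, {"blob": path_px},
                     len(path_px), p, rng, noise_sigma)
    return CineSeries(frames=frames, pixel_spacing=pixel_spacing,
                      frame_interval_ms=frame_interval_ms)
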