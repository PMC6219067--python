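"""Strain and strain-rate engine.

From the tracked landmark trajectories, the distance D(t) between an
atrioventricular junction and the mid-posterior LA point is converted into a
longitudinal strain curve

    eps(t) = (D(t) - D0) * 100 / D0        [%],   D0 = D at LV end-diastole,

and a strain-rate curve SR(t) = d(eps/100)/dt in 1/s.  Three cardiac phases
are read off the curves — LV end-systole (reservoir peak), diastasis and
pre-LA systole (the diastolic plateau), and the atrial kick — yielding the
six phasic function parameters:

* reservoir:  eps_s = eps at end-systole,  SR_s = peak positive SR;
* conduit:    eps_e = eps_s - eps_a,       SR_e = early-diastolic negative SR peak;
* booster:    eps_a = eps at pre-LA systole, SR_a = late-diastolic negative SR peak.

The decomposition is additive by construction: eps_e + eps_a = eps_s.
Parameters are computed per wall (septal/lateral on the 4-chamber view,
anterior/inferior on the 2-chamber view) and then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    CalibrationError,
    DomainError,
    MonophasicCurveError,
    ValidationError,
)
from .tracking import Trajectory

WALLS = ("septal", "lateral", "anterior", "inferior")


@dataclass
class DistanceCurve:
    """Junction-to-posterior-wall distance per frame, in mm."""

    wall: str
    d_mm: np.ndarray

    def __post_init__(self) -> None:
        self.d_mm = np.asarray(self.d_mm, dtype=float)
        if self.d_mm.ndim != 1 or len(self.d_mm) < 2:
            raise ValidationError("distance curve must be 1D with >= 2 frames")
        if not np.all(self.d_mm > 0):
            raise DomainError("distances must be strictly positive")

    @property
    def d0(self) -> float:
        return float(self.d_mm[0])


@dataclass
class StrainCurve:
    """Longitudinal strain in %, referenced to frame 0 (LV end-diastole)."""

    wall: str
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon[0] != 0.0:
            raise ValidationError("strain must be 0 at the reference frame")

    @property
    def n_frames(self) -> int:
        return len(self.epsilon)


@dataclass
class SRCurve:
    """Strain rate in 1/s (fractional strain per second)."""

    wall: str
    sr: np.ndarray

    def __post_init__(self) -> None:
        self.sr = np.asarray(self.sr, dtype=float)


@dataclass
class PhaseTimes:
    """Frame indices of the three read-off points.

    On the diastolic plateau, diastasis and pre-LA-systole onset coincide up
    to noise; both are reported as the single plateau index found at the |SR|
    minimum between the two diastolic SR lobes.
    """

    t_es: int
    t_diastasis: int
    t_preA: int

    def __post_init__(self) -> None:
        if not 0 < self.t_es < self.t_diastasis <= self.t_preA:
            raise ValidationError(
                f"phase ordering violated: es={self.t_es}, "
                f"diastasis={self.t_diastasis}, preA={self.t_preA}"
            )


@dataclass
class PhasicStrainResult:
    """The six headline LA function parameters plus the detected phase times."""

    eps_s: float  # reservoir strain, %
    eps_e: float  # conduit strain, %
    eps_a: float  # booster strain, %
    sr_s: float  # reservoir strain rate, 1/s (> 0)
    sr_e: float  # conduit strain rate, 1/s (< 0)
    sr_a: float  # booster strain rate, 1/s (< 0)
    phases: PhaseTimes | None = None
    wall: str = "global"

    def as_dict(self) -> dict[str, float]:
        return {
            "eps_s": self.eps_s,
            "eps_e": self.eps_e,
            "eps_a": self.eps_a,
            "sr_s": self.sr_s,
            "sr_e": self.sr_e,
            "sr_a": self.sr_a,
        }


def distance_curve(junction: Trajectory, posterior: Trajectory,
                   pixel_spacing: tuple[float, float], wall: str = "septal") -> DistanceCurve:
    """Euclidean distance in mm between two trajectories, anisotropic spacing."""
    if junction.n_frames != posterior.n_frames:
        raise ValidationError("trajectories must have equal length")
    row_mm, col_mm = pixel_spacing
    if row_mm <= 0 or col_mm <= 0:
        raise CalibrationError("pixel spacing must be positive")
    delta = junction.positions - posterior.positions
    d = np.hypot(delta[:, 0] * row_mm, delta[:, 1] * col_mm)
    if np.any(d <= 0):
        raise DomainError("degenerate geometry: zero junction-posterior distance")
    return DistanceCurve(wall=wall, d_mm=d)


def strain_curve(d: DistanceCurve) -> StrainCurve:
    """eps(t) = (D(t) - D0) * 100 / D0, in percent."""
    eps = (d.d_mm - d.d0) * 100.0 / d.d0
    eps[0] = 0.0
    return StrainCurve(wall=d.wall, epsilon=eps)


def _cyclic_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValidationError("smoothing window must be odd and >= 1")
    if window == 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.concatenate([x[-pad:], x, x[:pad]])
    return np.convolve(xp, kernel, mode="valid")


def strain_rate_curve(e: StrainCurve, frame_interval_ms: float,
                      smooth_window: int | None = None) -> SRCurve:
    """First-order derivative of the strain curve, in 1/s.

    Percent strain is converted to fractional strain before differentiation
    (SR magnitudes then come out in the physiologic ~1-2 /s range).  Central
    differences with cyclic wrap are used: the cine spans one full cardiac
    cycle, so frame T-1 neighbours frame 0.  Optional cyclic moving-average
    smoothing is applied to eps beforehand.
    """
    if frame_interval_ms <= 0:
        raise CalibrationError("frame interval must be positive")
    eps = e.epsilon
    if len(eps) < 3:
        raise ValidationError("need at least 3 frames to differentiate")
    if smooth_window:
        eps = _cyclic_moving_average(eps, smooth_window)
    dt = frame_interval_ms / 1000.0
    frac = eps / 100.0
    sr = (np.roll(frac, -1) - np.roll(frac, 1)) / (2.0 * dt)
    return SRCurve(wall=e.wall, sr=sr)


def reconstruct_strain(sr: SRCurve, frame_interval_ms: float) -> StrainCurve:
    """Invert the cyclic central-difference derivative back to strain in %.

    The cyclic central-difference operator is circulant, hence diagonal in
    Fourier space with symbol i*sin(2*pi*k/T)/dt; it is inverted mode by
    mode.  The DC mode is fixed by eps(0) = 0 and (for even T) the Nyquist
    mode, which the operator annihilates, is dropped.  For smooth strain
    curves both carry negligible energy, so the reconstruction matches the
    original to well under 0.1 absolute %.
    """
    if frame_interval_ms <= 0:
        raise CalibrationError("frame interval must be positive")
    dt = frame_interval_ms / 1000.0
    t = len(sr.sr)
    k = np.fft.fftfreq(t, d=1.0) * 2.0 * np.pi  # angular frequency per frame
    symbol = 1j * np.sin(k) / dt
    sr_hat = np.fft.fft(sr.sr)
    eps_hat = np.zeros_like(sr_hat)
    nonzero = np.abs(symbol) > 1e-12
    eps_hat[nonzero] = sr_hat[nonzero] / symbol[nonzero]
    eps = np.real(np.fft.ifft(eps_hat)) * 100.0
    eps -= eps[0]
    return StrainCurve(wall=sr.wall, epsilon=eps)


def _negative_local_minima(sr: np.ndarray, start: int) -> list[int]:
    """Indices in (start, T-1) that are strictly negative local minima of sr."""
    out = []
    for i in range(start + 1, len(sr) - 1):
        if sr[i] < 0 and sr[i] <= sr[i - 1] and sr[i] <= sr[i + 1]:
            out.append(i)
    # collapse flat-bottomed lobes to their first index
    collapsed = []
    for i in out:
        if collapsed and i == collapsed[-1] + 1 and sr[i] == sr[collapsed[-1]]:
            continue
        collapsed.append(i)
    return collapsed


def detect_phases(e: StrainCurve, sr: SRCurve) -> PhaseTimes:
    """Locate LV end-systole and the diastolic plateau on the curves.

    End-systole is the strain maximum.  After it the strain-rate curve must
    show two negative lobes — the early-diastolic (conduit) emptying and the
    late-diastolic atrial kick; the plateau index (diastasis / pre-LA
    systole) is the |SR| minimum between the two lobe peaks.

    Raises
    ------
    MonophasicCurveError
        If fewer than two negative SR lobes follow end-systole (e.g. no
        atrial kick).
    """
    eps = e.epsilon
    srv = sr.sr
    t_es = int(np.argmax(eps))
    if t_es == 0 or eps[t_es] <= 0:
        raise MonophasicCurveError("no positive reservoir lobe found")

    minima = _negative_local_minima(srv, t_es)
    if len(minima) < 2:
        raise MonophasicCurveError(
            f"only {len(minima)} negative SR lobe(s) after end-systole; "
            "cannot separate conduit from booster phase"
        )
    if len(minima) > 2:
        # keep the two deepest lobes, in temporal order
        deepest = sorted(sorted(minima, key=lambda i: srv[i])[:2])
    else:
        deepest = minima
    i1, i2 = deepest
    between = np.arange(i1 + 1, i2)
    if len(between) == 0:
        raise MonophasicCurveError("diastolic SR lobes are not separated by a plateau")
    t_plateau = int(between[np.argmin(np.abs(srv[between]))])
    return PhaseTimes(t_es=t_es, t_diastasis=t_plateau, t_preA=t_plateau)


def phasic_parameters(e: StrainCurve, sr: SRCurve, phases: PhaseTimes) -> PhasicStrainResult:
    """Read the six phasic parameters off the curves at the detected phases."""
    eps = e.epsilon
    srv = sr.sr
    t = len(eps)
    if not phases.t_preA < t:
        raise ValidationError("phase index beyond curve length")
    eps_s = float(eps[phases.t_es])
    eps_a = float(eps[phases.t_preA])
    eps_e = eps_s - eps_a
    sr_s = float(np.max(srv[: phases.t_es + 1]))
    sr_e = float(np.min(srv[phases.t_es + 1 : phases.t_preA + 1]))
    sr_a = float(np.min(srv[phases.t_preA + 1 :]))
    return PhasicStrainResult(
        eps_s=eps_s, eps_e=eps_e, eps_a=eps_a,
        sr_s=sr_s, sr_e=sr_e, sr_a=sr_a,
        phases=phases, wall=e.wall,
    )


def average_walls(results: list[PhasicStrainResult]) -> PhasicStrainResult:
    """Arithmetic mean of the per-wall parameters (2 walls per view, 4 for both).

    Phase times are reported as the per-wall medians (lower median, so the
    reported index is one actually observed).
    """
    if not results:
        raise ValidationError("cannot average an empty list of wall results")

    def lower_median(values: list[int]) -> int:
        v = sorted(values)
        return v[(len(v) - 1) // 2]

    mean = lambda attr: float(np.mean([getattr(r, attr) for r in results]))
    phases = None
    if all(r.phases is not None for r in results):
        phases = PhaseTimes(
            t_es=lower_median([r.phases.t_es for r in results]),
            t_diastasis=lower_median([r.phases.t_diastasis for r in results]),
            t_preA=lower_median([r.phases.t_preA for r in results]),
        )
    return PhasicStrainResult(
        eps_s=mean("eps_s"), eps_e=mean("eps_e"), eps_a=mean("eps_a"),
        sr_s=mean("sr_s"), sr_e=mean("sr_e"), sr_a=mean("sr_a"),
        phases=phases, wall="global",
    )
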