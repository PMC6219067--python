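"""Biplane area-length LA volumetry and emptying fractions.

Planimetry (LA areas and long-axis lengths on the 2- and 4-chamber views) is
taken as input — it is produced in external contouring software — and only
the printed formulas are applied:

    V [ml]        = 0.85 * A_2C * A_4C / L,  L = min(L_2C, L_4C)
    Total LAEF    = (LAV_max - LAV_min) * 100 / LAV_max
    Passive LAEF  = (LAV_max - LAV_preA) * 100 / LAV_max
    Active LAEF   = (LAV_preA - LAV_min) * 100 / LAV_preA

Areas in cm², lengths in cm, volumes in ml.  The three fractions satisfy
(1 - P/100)(1 - A/100) = 1 - T/100 identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

PHASES = ("max", "preA", "min")


def la_volume(a2c: float, a4c: float, l: float) -> float:
    """Biplane area-length LA volume in ml (areas cm², length cm)."""
    if l <= 0:
        raise DomainError(f"long-axis length must be positive, got {l}")
    if a2c < 0 or a4c < 0:
        raise DomainError("areas must be non-negative")
    return 0.85 * a2c * a4c / l


def choose_length(l_2c: float, l_4c: float) -> float:
    """The shorter of the two view long-axis lengths, in cm."""
    if l_2c <= 0 or l_4c <= 0:
        raise DomainError("lengths must be positive")
    return min(l_2c, l_4c)


def laef(lav_max: float, lav_prea: float, lav_min: float) -> tuple[float, float, float]:
    """(total, passive, active) LA emptying fractions in percent."""
    if lav_max <= 0 or lav_prea <= 0:
        raise DomainError("LAV_max and LAV_preA must be positive")
    total = (lav_max - lav_min) * 100.0 / lav_max
    passive = (lav_max - lav_prea) * 100.0 / lav_max
    active = (lav_prea - lav_min) * 100.0 / lav_prea
    return total, passive, active


@dataclass
class LAPlanimetry:
    """Per-phase LA areas (cm²) and long-axis lengths (cm) on both views.

    Keys of each dict are the phases ``max`` (LV end-systole), ``preA``
    (diastasis, before atrial contraction) and ``min`` (LV end-diastole).
    """

    a_2c: dict[str, float]
    a_4c: dict[str, float]
    l_2c: dict[str, float]
    l_4c: dict[str, float]

    def __post_init__(self) -> None:
        for name, d in (("a_2c", self.a_2c), ("a_4c", self.a_4c),
                        ("l_2c", self.l_2c), ("l_4c", self.l_4c)):
            missing = [p for p in PHASES if p not in d]
            if missing:
                raise ValidationError(f"{name} lacks phase(s) {missing}")
        for p in PHASES:
            if self.a_2c[p] < 0 or self.a_4c[p] < 0:
                raise DomainError(f"negative area at phase {p}")
            if (self.a_2c[p] > 0 or self.a_4c[p] > 0) and (
                self.l_2c[p] <= 0 or self.l_4c[p] <= 0
            ):
                raise DomainError(f"non-positive length with positive area at phase {p}")


@dataclass
class LAVolumeResult:
    """Phasic LA volumes (ml) and the three emptying fractions (%)."""

    lav_max: float
    lav_prea: float
    lav_min: float
    total_laef: float
    passive_laef: float
    active_laef: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lav_max_ml": self.lav_max,
            "lav_prea_ml": self.lav_prea,
            "lav_min_ml": self.lav_min,
            "total_laef_pct": self.total_laef,
            "passive_laef_pct": self.passive_laef,
            "active_laef_pct": self.active_laef,
        }


def volumes_from_planimetry(p: LAPlanimetry, bsa_m2: float | None = None) -> LAVolumeResult:
    """Apply the biplane formula at each phase and derive the emptying fractions.

    If ``bsa_m2`` is given, volumes are additionally divided by body surface
    area (reported then in ml/m²); the fractions are unaffected.
    """
    vols = {
        ph: la_volume(p.a_2c[ph], p.a_4c[ph], choose_length(p.l_2c[ph], p.l_4c[ph]))
        for ph in PHASES
    }
    total, passive, active = laef(vols["max"], vols["preA"], vols["min"])
    scale = 1.0 / bsa_m2 if bsa_m2 else 1.0
    if bsa_m2 is not None and bsa_m2 <= 0:
        raise DomainError("BSA must be positive")
    return LAVolumeResult(
        lav_max=vols["max"] * scale,
        lav_prea=vols["preA"] * scale,
        lav_min=vols["min"] * scale,
        total_laef=total, passive_laef=passive, active_laef=active,
    )


def read_planimetry_csv(path) -> LAPlanimetry:
    """Read rows ``phase, a2c_cm2, a4c_cm2, l2c_cm, l4c_cm`` into a planimetry set."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"phase", "a2c_cm2", "a4c_cm2", "l2c_cm", "l4c_cm"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"planimetry CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    rows = df.set_index("phase")
    try:
        return LAPlanimetry(
            a_2c={p: float(rows.loc[p, "a2c_cm2"]) for p in PHASES},
            a_4c={p: float(rows.loc[p, "a4c_cm2"]) for p in PHASES},
            l_2c={p: float(rows.loc[p, "l2c_cm"]) for p in PHASES},
            l_4c={p: float(rows.loc[p, "l4c_cm"]) for p in PHASES},
        )
    except KeyError as exc:
        raise ValidationError(f"planimetry CSV lacks phase row {exc}") from exc
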