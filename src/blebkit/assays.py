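"""Closed-form biophysical and immunological assay computations.

Cortical tension by micropipette aspiration (law of Laplace), the
two-micropipette adhesion frequency assay, the specific cytotoxic index of a
killing assay, and in-vivo homing indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AspirationMeasurement",
    "TensionResult",
    "AdhesionTrialSet",
    "KillingAssayRecord",
    "HomingRecord",
    "cortical_tension",
    "adhesion_frequency",
    "specific_cytotoxic_index",
    "homing_indices",
]


@dataclass(frozen=True)
class AspirationMeasurement:
    """Micropipette aspiration geometry.

    Rp: pipette inner radius (um); Rc: radius of the spherical cell portion
    outside the pipette (um); dp: suction pressure (Pa); Lp: aspirated tongue
    length (um). The Laplace relation is valid when the aspirated region is a
    hemisphere, i.e. Lp ~ Rp.
    """

    Rp_um: float
    Rc_um: float
    dp_Pa: float
    Lp_um: float | None = None

    def __post_init__(self) -> None:
        if not (self.Rc_um > self.Rp_um > 0):
            raise ValueError("need Rc > Rp > 0 for the Laplace relation")
        if self.dp_Pa < 0:
            raise ValueError("suction pressure must be non-negative")

    @property
    def in_validity_regime(self) -> bool:
        if self.Lp_um is None:
            return True
        return abs(self.Lp_um - self.Rp_um) / self.Rp_um <= 0.1


@dataclass(frozen=True)
class TensionResult:
    Tc_pN_um: float
    measurement: AspirationMeasurement
    valid: bool


@dataclass(frozen=True)
class AdhesionTrialSet:
    """Binary adhesion outcomes for one T cell-target pair (1 = adhesion)."""

    pair_id: int | str
    outcomes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.outcomes) == 0:
            raise ValueError("empty outcome list")
        if any(o not in (0, 1) for o in self.outcomes):
            raise ValueError("outcomes must be 0 or 1")

    @property
    def n_touches(self) -> int:
        return len(self.outcomes)

    @property
    def frequency(self) -> float:
        return sum(self.outcomes) / self.n_touches


@dataclass(frozen=True)
class KillingAssayRecord:
    experimental_death_pct: float
    spontaneous_death_pct: float
    maximum_death_pct: float
    et_ratio: str = ""

    def __post_init__(self) -> None:
        for v in (self.experimental_death_pct, self.spontaneous_death_pct,
                  self.maximum_death_pct):
            if not 0 <= v <= 100:
                raise ValueError("death percentages must lie in [0, 100]")


@dataclass(frozen=True)
class HomingRecord:
    pct_mcherry_tissue: float
    pct_mcherry_input: float
    pct_mcherry_blood_day6: float
    tissue: str = ""


def cortical_tension(m: AspirationMeasurement) -> TensionResult:
    """Cortical tension Tc = Rc*Rp / (2*(Rc - Rp)) * dp, in pN/um.

    With radii in um and pressure in Pa, Pa*um is numerically pN/um. The
    result carries a validity flag from the tongue-length criterion
    (|Lp - Rp| / Rp <= 0.1).
    """
    Tc = m.Rc_um * m.Rp_um / (2.0 * (m.Rc_um - m.Rp_um)) * m.dp_Pa
    return TensionResult(Tc_pN_um=Tc, measurement=m, valid=m.in_validity_regime)


def adhesion_frequency(
    trials: Iterable[AdhesionTrialSet],
) -> tuple[dict[int | str, float], dict[str, float]]:
    """Per-pair adhesion frequency and box-and-whisker cohort summary.

    Frequency = adhesion events / touches per pair; the summary reports
    median, quartiles and extrema across pairs.
    """
    per_pair = {t.pair_id: t.frequency for t in trials}
    if not per_pair:
        raise ValueError("no trial sets given")
    f = np.array(list(per_pair.values()))
    summary = {
        "n_pairs": float(f.size),
        "median": float(np.median(f)),
        "q1": float(np.quantile(f, 0.25)),
        "q3": float(np.quantile(f, 0.75)),
        "min": float(f.min()),
        "max": float(f.max()),
        "mean": float(f.mean()),
    }
    return per_pair, summary


def specific_cytotoxic_index(r: KillingAssayRecord) -> tuple[float, bool]:
    """Specific cytotoxic index (%) with an out-of-range warning flag.

    index = 100 * (experimental - spontaneous) / (maximum - spontaneous).
    Values outside [0, 100] (possible with noisy percentages) are returned
    as-is with the flag set rather than clamped.
    """
    denom = r.maximum_death_pct - r.spontaneous_death_pct
    if denom == 0:
        raise ZeroDivisionError(
            "maximum and spontaneous death coincide: index undefined"
        )
    index = 100.0 * (r.experimental_death_pct - r.spontaneous_death_pct) / denom
    return index, not (0.0 <= index <= 100.0)


def homing_indices(h: HomingRecord) -> tuple[float, float]:
    """(homing index, blood-normalized fraction).

    HI = %mCherry+ tissue / %mCherry+ input; the second ratio normalizes the
    tissue fraction to the day-6 blood fraction instead.
    """
    if h.pct_mcherry_input <= 0:
        raise ZeroDivisionError("input percentage must be positive for HI")
    hi = h.pct_mcherry_tissue / h.pct_mcherry_input
    if h.pct_mcherry_blood_day6 <= 0:
        raise ZeroDivisionError("day-6 blood percentage must be positive")
    norm_blood = h.pct_mcherry_tissue / h.pct_mcherry_blood_day6
    return hi, norm_blood
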