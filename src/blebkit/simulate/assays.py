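"""Ground-truthed synthetic assay tables (aspiration and killing assays).

Aspiration records are generated by inverting the Laplace relation: a true
tension and a pipette/cell geometry are drawn, then the suction pressure that
would be observed is computed, so the tension estimator must recover the
ground truth exactly. Killing-assay records are likewise built by inverting
the specific-cytotoxic-index formula around a known true index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..assays import AspirationMeasurement, KillingAssayRecord

__all__ = ["SimulatedAspiration", "simulate_aspiration", "simulate_killing_assay"]


@dataclass(frozen=True)
class SimulatedAspiration:
    measurement: AspirationMeasurement
    true_Tc_pN_um: float


def simulate_aspiration(
    n: int,
    tension_range_pN_um: tuple[float, float] = (50.0, 400.0),
    rp_range_um: tuple[float, float] = (1.5, 3.0),
    seed: int | None = 0,
) -> list[SimulatedAspiration]:
    """Draw n aspiration records with known true cortical tensions.

    For each record a tension Tc and geometry (Rp, and Rc > Rp) are drawn
    uniformly, the pressure is set to dp = Tc * 2 (Rc - Rp) / (Rc Rp), and the
    tongue length Lp is set equal to Rp (the validity regime).
    """
    lo_t, hi_t = tension_range_pN_um
    lo_r, hi_r = rp_range_um
    if lo_t <= 0 or lo_r <= 0:
        raise ValueError("tension and radius ranges must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        Tc = float(rng.uniform(lo_t, hi_t))
        Rp = float(rng.uniform(lo_r, hi_r))
        Rc = float(Rp * rng.uniform(1.5, 3.0))  # cell strictly wider than pipette
        dp = Tc * 2.0 * (Rc - Rp) / (Rc * Rp)
        out.append(
            SimulatedAspiration(
                measurement=AspirationMeasurement(Rp_um=Rp, Rc_um=Rc,
                                                  dp_Pa=dp, Lp_um=Rp),
                true_Tc_pN_um=Tc,
            )
        )
    return out


def simulate_killing_assay(
    spontaneous_pct: float = 4.51,
    maximum_pct: float = 80.0,
    true_index_pct: float | np.ndarray = 50.0,
    et_ratios: list[str] | None = None,
) -> pd.DataFrame:
    """Killing-assay table whose experimental death reproduces a known index.

    ``experimental = spontaneous + index/100 * (maximum - spontaneous)``; the
    default spontaneous death of 4.51% matches the reported target-cells-alone
    control. ``true_index_pct`` may be a scalar or one value per E:T ratio.
    """
    if not 0 <= spontaneous_pct < maximum_pct <= 100:
        raise ValueError("need 0 <= spontaneous < maximum <= 100")
    idx = np.atleast_1d(np.asarray(true_index_pct, dtype=float))
    if np.any(idx < 0) or np.any(idx > 100):
        raise ValueError("true index must lie in [0, 100]")
    if et_ratios is None:
        et_ratios = [f"{2**k}:1" for k in range(len(idx))]
    if len(et_ratios) != len(idx):
        raise ValueError("one E:T label per true index required")
    rows = []
    for label, i in zip(et_ratios, idx):
        exp = spontaneous_pct + i / 100.0 * (maximum_pct - spontaneous_pct)
        rec = KillingAssayRecord(
            experimental_death_pct=exp,
            spontaneous_death_pct=spontaneous_pct,
            maximum_death_pct=maximum_pct,
            et_ratio=label,
        )
        rows.append(
            {
                "et_ratio": label,
                "experimental_death_pct": rec.experimental_death_pct,
                "spontaneous_death_pct": rec.spontaneous_death_pct,
                "maximum_death_pct": rec.maximum_death_pct,
                "true_index_pct": float(i),
            }
        )
    return pd.DataFrame(rows)
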