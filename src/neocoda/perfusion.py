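"""Bedside oxygenation and perfusion physiology.

Two derived quantities link pulse oximetry, tissue spectrometry and
Doppler sonography to gut oxygen supply:

* fractional tissue oxygen extraction, FTOE = (SpO2 - regional SO2)/SpO2,
  the fraction of delivered oxygen extracted by the tissue under the probe
  (liver or periumbilical region);
* global gut perfusion, the portal-vein volume blood flow
  Q = mean velocity * cross-sectional area * 60 s, in ml/min, optionally
  normalised per kg body weight.

Negative FTOE (regional SO2 above SpO2) is physically possible measurement
noise and is logged, not rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_tables import PerfusionRecord

__all__ = ["PerfusionDerived", "iftoe", "global_gut_perfusion",
           "normalize_per_weight", "derive_perfusion", "perfusion_summary"]

logger = logging.getLogger(__name__)


@dataclass
class PerfusionDerived:
    subject_id: str
    iftoe: Optional[float]
    gut_perfusion: Optional[float]          # ml/min
    gut_perfusion_per_kg: Optional[float]   # (ml/min)/kg


def iftoe(spo2: float, regional_so2: float) -> float:
    """Fractional tissue oxygen extraction (SpO2 - SO2)/SpO2, both in %."""
    if spo2 <= 0:
        raise ValueError(f"SpO2 must be > 0, got {spo2}")
    if not (0 <= spo2 <= 100 and 0 <= regional_so2 <= 100):
        raise ValueError("saturations must be within [0, 100]%")
    value = (spo2 - regional_so2) / spo2
    if value < 0:
        logger.warning("negative FTOE %.4f (regional SO2 %.1f above SpO2 %.1f)",
                       value, regional_so2, spo2)
    return value


def global_gut_perfusion(mean_velocity: float, diameter: float) -> float:
    """Portal-vein volume flow: velocity [cm/s] * pi*(d/2)^2 [cm^2] * 60 s,
    in ml/min (1 cm^3 = 1 ml)."""
    if mean_velocity < 0 or diameter < 0:
        raise ValueError("velocity and diameter must be >= 0")
    return mean_velocity * math.pi * (diameter / 2.0) ** 2 * 60.0


def normalize_per_weight(q: float, weight: float) -> float:
    """Per-kg normalisation of a flow for interindividual comparison."""
    if weight <= 0:
        raise ValueError(f"body weight must be > 0, got {weight}")
    return q / weight


def derive_perfusion(records: Iterable[PerfusionRecord],
                     so2_field: str = "ru_so2") -> list[PerfusionDerived]:
    """Compute FTOE and global gut perfusion for each record.

    ``so2_field`` selects the regional SO2 fed to the extraction formula
    ('ru_so2' = periumbilical/intestinal, default, or 'rl_so2' = liver).
    Missing inputs yield None for the affected quantity.
    """
    if so2_field not in ("ru_so2", "rl_so2"):
        raise ValueError("so2_field must be 'ru_so2' or 'rl_so2'")
    out = []
    for r in records:
        so2 = getattr(r, so2_field)
        ext = iftoe(r.spo2, so2) if r.spo2 is not None and so2 is not None else None
        q = qkg = None
        if r.pv_mean_velocity is not None and r.pv_diameter_cm is not None:
            q = global_gut_perfusion(r.pv_mean_velocity, r.pv_diameter_cm)
            if r.body_weight_kg is not None:
                qkg = normalize_per_weight(q, r.body_weight_kg)
        out.append(PerfusionDerived(r.subject_id, ext, q, qkg))
    return out


def perfusion_summary(records: Sequence[PerfusionRecord],
                      derived: Sequence[PerfusionDerived],
                      spo2_cut: float = 90.0) -> pd.DataFrame:
    """Mean +/- SD of measured and derived parameters for the whole cohort
    and the low/high oxygenation subgroups (SpO2 <= cut vs > cut)."""
    raw = pd.DataFrame([vars(r) for r in records]).set_index("subject_id")
    der = pd.DataFrame([vars(d) for d in derived]).set_index("subject_id")
    frame = raw.join(der)
    groups = {
        f"SpO2<={spo2_cut:g}": frame[frame["spo2"] <= spo2_cut],
        f"SpO2>{spo2_cut:g}": frame[frame["spo2"] > spo2_cut],
        "total": frame,
    }
    rows = {}
    for name, sub in groups.items():
        num = sub.select_dtypes("number")
        rows[name] = {
            "n": len(sub),
            **{f"{c}_mean": num[c].mean() for c in num.columns},
            **{f"{c}_sd": num[c].std(ddof=1) for c in num.columns},
        }
    return pd.DataFrame.from_dict(rows, orient="index")
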