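"""Lumping recipe that reduces an organ-level PBPK table to minimal-model parameters.

The minimal model collapses all non-brain organs of a whole-body antibody
PBPK model into a single tissue compartment with vascular, endosomal and
interstitial sub-spaces.  The operations here implement that reduction for
any organ table:

* volumes are summed per sub-space (:func:`lump_volumes`),
* the four CSF spaces (lateral ventricle, third/fourth ventricle, cisterna
  magna, subarachnoid space) are summed into one CSF volume (:func:`lump_csf`),
* tissue plasma flow is total (lung) flow minus brain flow and tissue lymph
  flow is 0.2% of it (:func:`partition_flows`),
* the single tissue vascular reflection coefficient is the vascular-volume-
  weighted mean of the per-organ coefficients (:func:`weighted_sigma`),
* brain lymph flow is the sum of brain ISF and CSF bulk flows
  (:func:`brain_lymph`).

All operations are order-insensitive in the organ list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SIGMA_LOOSE",
    "SIGMA_MEDIUM",
    "SIGMA_TIGHT",
    "OrganEntry",
    "ReductionError",
    "lump_volumes",
    "lump_csf",
    "partition_flows",
    "weighted_sigma",
    "brain_lymph",
    "read_organ_table",
    "write_organ_table",
]

# Vascular-leakiness categories used for per-organ reflection coefficients.
SIGMA_LOOSE = 0.85
SIGMA_MEDIUM = 0.90
SIGMA_TIGHT = 0.95

ORGAN_COLUMNS = ("organ", "V_vascular", "V_endosomal", "V_interstitial",
                 "sigma_vascular", "Q_plasma")


class ReductionError(ValueError):
    """Raised for degenerate lumping inputs."""


@dataclass(frozen=True)
class OrganEntry:
    """One organ row of a full-model parameter table (volumes L, flow L/h)."""

    organ_name: str
    V_vascular: float
    V_endosomal: float
    V_interstitial: float
    sigma_vascular: float
    Q_plasma: float

    def __post_init__(self) -> None:
        for name in ("V_vascular", "V_endosomal", "V_interstitial", "Q_plasma"):
            if getattr(self, name) < 0:
                raise ReductionError(f"{self.organ_name}: {name} must be non-negative")
        if not 0.0 <= self.sigma_vascular <= 1.0:
            raise ReductionError(
                f"{self.organ_name}: sigma_vascular must lie in [0, 1], "
                f"got {self.sigma_vascular}"
            )


def lump_volumes(organs: Sequence[OrganEntry]) -> tuple[float, float, float]:
    """Sum organ volumes into (V_Tv, V_Te, V_Ti)."""
    organs = list(organs)
    if not organs:
        raise ReductionError("organ list must be non-empty")
    v_tv = sum(o.V_vascular for o in organs)
    v_te = sum(o.V_endosomal for o in organs)
    v_ti = sum(o.V_interstitial for o in organs)
    return v_tv, v_te, v_ti


def lump_csf(v_LV: float, v_TFV: float, v_CM: float, v_SAS: float) -> float:
    """Combine the four CSF spaces into a single CSF volume."""
    vols = (v_LV, v_TFV, v_CM, v_SAS)
    if any(v < 0 for v in vols):
        raise ReductionError(f"CSF volumes must be non-negative, got {vols}")
    return float(sum(vols))


def partition_flows(Q_lung: float, Q_brain: float) -> tuple[float, float]:
    """Tissue plasma flow and tissue lymph flow from total and brain flow.

    Total plasma flow equals lung plasma flow, so the lumped tissue
    compartment receives Q_T = Q_lung - Q_brain; tissue lymph flow is 0.2%
    of tissue plasma flow.
    """
    if not Q_brain > 0:
        raise ReductionError(f"Q_brain must be positive, got {Q_brain}")
    if not Q_lung > Q_brain:
        raise ReductionError(
            f"Q_lung ({Q_lung}) must exceed Q_brain ({Q_brain})"
        )
    q_t = Q_lung - Q_brain
    return q_t, 0.002 * q_t


def weighted_sigma(organs: Sequence[OrganEntry]) -> float:
    """Vascular-volume-weighted mean reflection coefficient."""
    organs = list(organs)
    if not organs:
        raise ReductionError("organ list must be non-empty")
    total = sum(o.V_vascular for o in organs)
    if not total > 0:
        raise ReductionError("total vascular volume must be positive")
    return sum(o.sigma_vascular * o.V_vascular for o in organs) / total


def brain_lymph(Q_B_ECF: float, Q_B_CSF: float) -> float:
    """Brain lymph flow: sum of brain ISF and CSF bulk flows."""
    if Q_B_ECF < 0 or Q_B_CSF < 0:
        raise ReductionError(
            f"flows must be non-negative, got ({Q_B_ECF}, {Q_B_CSF})"
        )
    return Q_B_ECF + Q_B_CSF


# ---------------------------------------------------------------------------
# organ-table I/O


def read_organ_table(path) -> list[OrganEntry]:
    """Read an organ table CSV with the fixed header ``organ,V_vascular,...``."""
    df = pd.read_csv(path)
    missing = set(ORGAN_COLUMNS) - set(df.columns)
    if missing:
        raise ReductionError(f"organ table missing columns: {sorted(missing)}")
    return [
        OrganEntry(
            organ_name=str(r["organ"]),
            V_vascular=float(r["V_vascular"]),
            V_endosomal=float(r["V_endosomal"]),
            V_interstitial=float(r["V_interstitial"]),
            sigma_vascular=float(r["sigma_vascular"]),
            Q_plasma=float(r["Q_plasma"]),
        )
        for _, r in df.iterrows()
    ]


def write_organ_table(organs: Iterable[OrganEntry], path) -> None:
    """Write organs to CSV in the fixed column order."""
    rows = [
        {
            "organ": o.organ_name,
            "V_vascular": o.V_vascular,
            "V_endosomal": o.V_endosomal,
            "V_interstitial": o.V_interstitial,
            "sigma_vascular": o.sigma_vascular,
            "Q_plasma": o.Q_plasma,
        }
        for o in organs
    ]
    pd.DataFrame(rows, columns=ORGAN_COLUMNS).to_csv(path, index=False)
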