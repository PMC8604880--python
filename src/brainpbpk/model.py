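"""The 16-state ODE system of the minimal brain PBPK model.

States are molar antibody concentrations, except three free-FcRn
concentrations (one per endosomal space).  Fixed ordering::

     0  C_plasma              plasma
     1  C_tissue_vasc         lumped tissue vascular space
     2  C_tissue_endo_unbound tissue endosome, unbound antibody
     3  C_tissue_endo_bound   tissue endosome, FcRn-bound antibody
     4  R_FcRn_tissue         tissue endosome, free FcRn
     5  C_tissue_isf          lumped tissue interstitium
     6  C_brain_vasc          brain vascular space
     7  C_bbb_endo_unbound    BBB endothelial endosome, unbound
     8  C_bbb_endo_bound      BBB endosome, FcRn-bound
     9  R_FcRn_bbb            BBB endosome, free FcRn
    10  C_brain_isf           brain interstitial fluid (ISF)
    11  C_bcsfb_endo_unbound  BCSFB epithelial endosome, unbound
    12  C_bcsfb_endo_bound    BCSFB endosome, FcRn-bound
    13  R_FcRn_bcsfb          BCSFB endosome, free FcRn
    14  C_csf                 lumped cerebrospinal fluid (CSF)
    15  C_lymph               lymph

Fluxes are written as amounts per hour (flow x concentration, or clearance
x concentration) and divided by the receiving compartment volume.  Vascular
escape is convective: a barrier with reflection coefficient sigma passes a
fraction (1 - sigma) of the carrying flow.  Pinocytotic uptake into each
endosomal space is symmetric from the luminal and abluminal sides; unbound
endosomal antibody either binds FcRn (kon/koff) or is degraded at k_deg;
FcRn-bound antibody is exported at the uptake clearance rate, a fraction FR
(FR_B in brain) returning to the vascular side and the rest delivered
across the barrier.  The receptor is returned to the free pool on export.
ISF drains to CSF by bulk ECF flow, and both ISF and CSF are cleared
glymphatically to the lymph compartment, which drains to plasma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import (
    DerivedParams,
    ParameterError,
    SpeciesParams,
    SubjectSpec,
    derive_params,
)

__all__ = [
    "N_STATES",
    "STATE_NAMES",
    "FCRN_STATE_INDEX",
    "DRUG_STATE_INDEX",
    "DoseEvent",
    "ModelError",
    "rhs",
    "build_system",
    "initial_state",
    "drug_volumes",
    "total_drug_amount",
    "dose_to_plasma_concentration",
]

N_STATES = 16

STATE_NAMES = (
    "C_plasma",
    "C_tissue_vasc",
    "C_tissue_endo_unbound",
    "C_tissue_endo_bound",
    "R_FcRn_tissue",
    "C_tissue_isf",
    "C_brain_vasc",
    "C_bbb_endo_unbound",
    "C_bbb_endo_bound",
    "R_FcRn_bbb",
    "C_brain_isf",
    "C_bcsfb_endo_unbound",
    "C_bcsfb_endo_bound",
    "R_FcRn_bcsfb",
    "C_csf",
    "C_lymph",
)

#: Free-FcRn states, one per endosomal space.
FCRN_STATE_INDEX = (4, 9, 13)

#: Antibody-carrying states (FcRn-bound complexes count as drug).
DRUG_STATE_INDEX = tuple(i for i in range(N_STATES) if i not in FCRN_STATE_INDEX)

# (unbound, free-FcRn, bound) index triples for the bilinear binding terms.
_BINDING_TRIPLES = ((2, 4, 3), (7, 9, 8), (11, 13, 12))


class ModelError(ValueError):
    """Raised for invalid model inputs (bad state dimension, NaN parameters)."""


@dataclass(frozen=True)
class DoseEvent:
    """A dose administered directly into plasma (IV bolus), in mg per kg."""

    time: float
    dose: float
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ModelError(f"dose time must be >= 0, got {self.time}")
        if self.dose < 0:
            raise ModelError(f"dose must be >= 0, got {self.dose}")
        if self.route != "iv_bolus":
            raise ModelError(f"unsupported route {self.route!r}; only 'iv_bolus'")


def drug_volumes(p: SpeciesParams) -> np.ndarray:
    """Physical volume (L) carried by each state; 0 for free-FcRn states."""
    v = np.zeros(N_STATES)
    v[0] = p.V_P
    v[1] = p.V_Tv
    v[2] = v[3] = p.V_Te
    v[5] = p.V_Ti
    v[6] = p.V_Bv
    v[7] = v[8] = p.V_BE_BBB
    v[10] = p.V_Bi
    v[11] = v[12] = p.V_BE_BCSFB
    v[14] = p.V_CSF
    v[15] = p.V_L
    return v


def total_drug_amount(state: np.ndarray, p: SpeciesParams) -> float:
    """Total antibody amount (mol) summed over all compartments."""
    state = np.asarray(state, dtype=float)
    return float(drug_volumes(p)[DRUG_STATE_INDEX] @ state[list(DRUG_STATE_INDEX)])


def _linear_matrix(p: SpeciesParams, d: DerivedParams, n: int) -> np.ndarray:
    """Constant part of the system: everything except the kon binding terms."""
    A = np.zeros((n, n))
    CLT, CLBBB, CLBCSFB = d.CLUP_T, d.CLUP_BBB, d.CLUP_BCSFB
    kon, koff, kdeg = p.kon_FcRn, p.koff_FcRn, p.k_deg

    # plasma
    A[0, 0] = -(p.Q_T + p.Q_B) / p.V_P
    A[0, 1] = (p.Q_T - p.L_T) / p.V_P
    A[0, 6] = (p.Q_B - p.L_B) / p.V_P
    A[0, 15] = (p.L_T + p.L_B) / p.V_P
    # tissue vascular
    A[1, 0] = p.Q_T / p.V_Tv
    A[1, 1] = -((p.Q_T - p.L_T) + p.L_T * (1 - p.sigma_Tv) + CLT) / p.V_Tv
    A[1, 3] = CLT * p.FR / p.V_Tv
    # tissue endosome (unbound / bound / free FcRn)
    A[2, 1] = CLT / p.V_Te
    A[2, 5] = CLT / p.V_Te
    A[2, 3] = koff
    A[2, 2] = -kdeg
    A[3, 3] = -(koff + CLT / p.V_Te)
    A[4, 3] = koff + CLT / p.V_Te
    # tissue interstitium
    A[5, 1] = p.L_T * (1 - p.sigma_Tv) / p.V_Ti
    A[5, 3] = CLT * (1 - p.FR) / p.V_Ti
    A[5, 5] = -(p.L_T * (1 - p.sigma_TL) + CLT) / p.V_Ti
    # brain vascular
    A[6, 0] = p.Q_B / p.V_Bv
    A[6, 6] = -(
        (p.Q_B - p.L_B)
        + p.Q_B_ECF * (1 - p.sigma_BBB)
        + p.Q_B_CSF * (1 - p.sigma_BCSFB)
        + CLBBB
        + CLBCSFB
    ) / p.V_Bv
    A[6, 8] = p.FR_B * CLBBB / p.V_Bv
    A[6, 12] = p.FR_B * CLBCSFB / p.V_Bv
    # BBB endosome
    A[7, 6] = CLBBB / p.V_BE_BBB
    A[7, 10] = CLBBB / p.V_BE_BBB
    A[7, 8] = koff
    A[7, 7] = -kdeg
    A[8, 8] = -(koff + CLBBB / p.V_BE_BBB)
    A[9, 8] = koff + CLBBB / p.V_BE_BBB
    # brain ISF: paracellular inflow, transcytosed delivery, endosomal uptake,
    # bulk flow to CSF, glymphatic outflow to lymph
    A[10, 6] = p.Q_B_ECF * (1 - p.sigma_BBB) / p.V_Bi
    A[10, 8] = CLBBB * (1 - p.FR_B) / p.V_Bi
    A[10, 10] = -(CLBBB + p.Q_B_ECF + p.Q_B_ECF * (1 - p.sigma_ISF)) / p.V_Bi
    # BCSFB endosome
    A[11, 6] = CLBCSFB / p.V_BE_BCSFB
    A[11, 14] = CLBCSFB / p.V_BE_BCSFB
    A[11, 12] = koff
    A[11, 11] = -kdeg
    A[12, 12] = -(koff + CLBCSFB / p.V_BE_BCSFB)
    A[13, 12] = koff + CLBCSFB / p.V_BE_BCSFB
    # CSF
    A[14, 6] = p.Q_B_CSF * (1 - p.sigma_BCSFB) / p.V_CSF
    A[14, 12] = CLBCSFB * (1 - p.FR_B) / p.V_CSF
    A[14, 10] = p.Q_B_ECF / p.V_CSF
    A[14, 14] = -(CLBCSFB + p.Q_B_CSF * (1 - p.sigma_CSF)) / p.V_CSF
    # lymph
    A[15, 5] = p.L_T * (1 - p.sigma_TL) / p.V_L
    A[15, 10] = p.Q_B_ECF * (1 - p.sigma_ISF) / p.V_L
    A[15, 14] = p.Q_B_CSF * (1 - p.sigma_CSF) / p.V_L
    A[15, 15] = -(p.L_T + p.L_B) / p.V_L

    if n > N_STATES:
        # bookkeeping state: cumulative degraded amount (mol)
        A[16, 2] = kdeg * p.V_Te
        A[16, 7] = kdeg * p.V_BE_BBB
        A[16, 11] = kdeg * p.V_BE_BCSFB
    return A


def build_system(
    p: SpeciesParams,
    d: DerivedParams | None = None,
    track_degradation: bool = False,
) -> tuple[Callable, Callable, int]:
    """Compile the ODE right-hand side and its analytic Jacobian.

    Returns ``(f, jac, n)`` with ``f(t, y) -> dy/dt``.  With
    ``track_degradation`` a 17th state accumulates the degraded amount
    (mol) for mass-balance audits.
    """
    if d is None:
        d = derive_params(p)
    for name, v in list(p.as_dict().items()):
        if name == "species_id":
            continue
        if not math.isfinite(v) or v < 0:
            raise ModelError(f"parameter {name} must be finite and >= 0, got {v}")
    n = N_STATES + 1 if track_degradation else N_STATES
    A = _linear_matrix(p, d, n)
    kon = p.kon_FcRn

    def f(t: float, y: np.ndarray) -> np.ndarray:
        if y.shape[-1] != n:
            raise ModelError(f"state dimension must be {n}, got {y.shape[-1]}")
        dy = A @ y
        for iu, ir, ib in _BINDING_TRIPLES:
            rate = kon * y[iu] * y[ir]
            dy[iu] -= rate
            dy[ib] += rate
            dy[ir] -= rate
        return dy

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        J = A.copy()
        for iu, ir, ib in _BINDING_TRIPLES:
            ku, kr = kon * y[ir], kon * y[iu]
            J[iu, iu] -= ku
            J[iu, ir] -= kr
            J[ib, iu] += ku
            J[ib, ir] += kr
            J[ir, iu] -= ku
            J[ir, ir] -= kr
        return J

    return f, jac, n


def rhs(
    t: float,
    state: np.ndarray,
    p: SpeciesParams,
    d: DerivedParams | None = None,
) -> np.ndarray:
    """Time derivative of the 16-state system at *state* (convenience form).

    For repeated evaluation (e.g. inside a solver) use :func:`build_system`,
    which precomputes the constant coefficient matrix.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ModelError(f"state must have shape ({N_STATES},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ModelError("state contains non-finite values")
    f, _, _ = build_system(p, d)
    return f(t, state)


def dose_to_plasma_concentration(
    dose_mg_per_kg: float, subject: SubjectSpec, p: SpeciesParams
) -> float:
    """Molar plasma concentration increment of an IV bolus.

    dose (mg/kg) x body weight (kg) / 1000 -> g; / molecular weight -> mol;
    / plasma volume -> M.
    """
    amount_mol = dose_mg_per_kg * subject.body_weight / 1000.0 / subject.molecular_weight
    return amount_mol / p.V_P


def initial_state(
    dose: DoseEvent,
    subject: SubjectSpec,
    p: SpeciesParams,
    track_degradation: bool = False,
) -> np.ndarray:
    """State immediately after a t = 0 IV bolus.

    All antibody states are zero except plasma; the three free-FcRn pools
    start at the total FcRn concentration.
    """
    if dose.time != 0:
        raise ModelError(f"initial_state expects a t = 0 dose, got t = {dose.time}")
    n = N_STATES + 1 if track_degradation else N_STATES
    y0 = np.zeros(n)
    y0[0] = dose_to_plasma_concentration(dose.dose, subject, p)
    for i in FCRN_STATE_INDEX:
        y0[i] = p.FcRn_total
    return y0
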