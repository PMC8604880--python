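"""One-at-a-time (OAT) lognormal sensitivity analysis of antibody exposure.

Each model parameter is perturbed in isolation by a multiplier drawn from a
lognormal distribution (mu = 0, sigma = 0.25 on the log scale); derived
transport parameters are recomputed after every perturbation, the model is
re-simulated, and the percentage change in exposure

    S_x (%) = (AUC_perturbed / AUC_base - 1) * 100

is recorded for plasma, brain ISF and CSF.  The default design perturbs 27
parameters with 1000 samples each for a 70 kg human given a single
10 mg/kg IV bolus over 1000 h at a 1 h output step.

Each parameter owns an RNG stream derived from the master seed and the
parameter's name, so extending the parameter list never shifts the draws
of existing parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DoseEvent
from .parameters import (
    SpeciesParams,
    SubjectSpec,
    derive_params,
    species_params,
)
from .simulation import SimulationResult, SolverConfig, auc, simulate

__all__ = [
    "DEFAULT_SENSITIVITY_PARAMETERS",
    "SENSITIVITY_COMPARTMENTS",
    "SensitivityConfig",
    "SensitivityResult",
    "draw_multipliers",
    "sensitivity_metric",
    "perturb_params",
    "run_oat",
]

#: The 27 perturbed parameters of the reference design.  Lymph flows L_T and
#: L_B, the glymphatic CSF reflection coefficient and the barrier surface
#: areas are excluded (the flows are themselves derived quantities).
DEFAULT_SENSITIVITY_PARAMETERS = (
    "FcRn_total", "k_deg", "FR", "FR_B", "kon_FcRn", "koff_FcRn",
    "V_P", "V_Tv", "V_Te", "V_Ti", "V_Bv", "V_BE_BBB", "V_BE_BCSFB",
    "V_Bi", "V_CSF", "V_L", "Q_T", "Q_B", "Q_B_ECF", "Q_B_CSF",
    "k_CLUP_T", "k_CLUP_B", "sigma_Tv", "sigma_TL", "sigma_BBB",
    "sigma_BCSFB", "sigma_ISF",
)

SENSITIVITY_COMPARTMENTS = ("plasma", "ISF", "CSF")

#: Parameters that are fractions: clamped to [0, 1] after multiplication so a
#: perturbation cannot produce a physically inadmissible value (e.g. a
#: reflection coefficient above 1 implying negative convective flux).
_CLAMPED_TO_UNIT = frozenset(
    {"FR", "FR_B", "sigma_Tv", "sigma_TL", "sigma_BBB",
     "sigma_BCSFB", "sigma_ISF", "sigma_CSF"}
)


@dataclass(frozen=True)
class SensitivityConfig:
    """Design of an OAT sensitivity run (defaults = the reference design)."""

    parameters: tuple = DEFAULT_SENSITIVITY_PARAMETERS
    n_samples: int = 1000
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 0.25
    species: str = "human"
    body_weight: float = 70.0
    molecular_weight: float = 150_000.0
    dose: float = 10.0          # mg/kg, single IV bolus at t = 0
    t_end: float = 1000.0       # h
    dt_out: float = 1.0         # h
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.lognorm_sigma <= 0:
            raise ValueError(f"lognorm_sigma must be > 0, got {self.lognorm_sigma}")


@dataclass
class SensitivityResult:
    """Long-format samples plus per-(parameter, compartment) summaries.

    ``samples`` columns: parameter, compartment, sample_index, multiplier,
    S_percent (NaN for failed runs).  ``summary`` columns: median, q1, q3,
    min, max of S, the rank metrics ``mean_abs_S`` / ``median_abs_S``, plus
    n and n_failed.

    Parameters are ranked by mean |S|, the expected absolute percentage
    change in exposure.  The signed median of S is reported but not used
    for ranking: under a symmetric multiplier design it converges to zero
    for every parameter as n grows, and for a parameter sitting at its
    physical bound (sigma_BBB = 1, where upward perturbations clamp to the
    bound and leave exposure unchanged) any median-based statistic is
    unstable at the 50th-percentile boundary.  The mean of |S| captures the
    one-sided heavy response of such boundary parameters robustly.
    """

    samples: pd.DataFrame
    summary: pd.DataFrame
    base_auc: dict
    config: SensitivityConfig

    def rank(self, compartment: str) -> pd.DataFrame:
        """Parameters ordered by mean |S| (descending) for one compartment."""
        sub = self.summary[self.summary["compartment"] == compartment]
        return sub.sort_values("mean_abs_S", ascending=False).reset_index(drop=True)

    def top_parameters(self, compartment: str, k: int = 3) -> list[str]:
        return list(self.rank(compartment)["parameter"].head(k))

    def to_csv(self, samples_path, summary_path=None) -> None:
        self.samples.to_csv(samples_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False)


def _param_rng(master_seed: int, parameter: str) -> np.random.Generator:
    """Independent, name-addressed RNG stream for one parameter."""
    key = tuple(parameter.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=key))


def draw_multipliers(
    n: int,
    sigma: float = 0.25,
    mu: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw *n* lognormal perturbation multipliers (log-scale mean mu, sd sigma)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def sensitivity_metric(auc_perturbed: float, auc_base: float) -> float:
    """Percentage change in exposure relative to the base simulation."""
    if auc_base <= 0:
        raise ValueError(f"base AUC must be positive, got {auc_base}")
    return (auc_perturbed / auc_base - 1.0) * 100.0


def perturb_params(p: SpeciesParams, parameter: str, multiplier: float) -> SpeciesParams:
    """Return a copy of *p* with one parameter multiplied.

    Fraction-valued parameters (FR, FR_B and the reflection coefficients)
    are clamped to [0, 1] after multiplication.
    """
    if not hasattr(p, parameter) or parameter == "species_id":
        raise KeyError(f"unknown model parameter {parameter!r}")
    value = getattr(p, parameter) * multiplier
    if parameter in _CLAMPED_TO_UNIT:
        value = min(max(value, 0.0), 1.0)
    return p.replace(**{parameter: value})


def run_oat(
    config: SensitivityConfig,
    base_params: SpeciesParams | None = None,
    multipliers: dict[str, np.ndarray] | None = None,
) -> SensitivityResult:
    """Run the one-at-a-time sensitivity analysis.

    *multipliers* can override the drawn multiplier vectors per parameter
    (e.g. all-ones for a null check).  Failed perturbed simulations are
    recorded with S = NaN and a warning; they are excluded from summaries.
    """
    p0 = base_params if base_params is not None else species_params(config.species)
    subject = SubjectSpec(
        body_weight=config.body_weight, molecular_weight=config.molecular_weight
    )
    dose = DoseEvent(time=0.0, dose=config.dose)

    def run(params: SpeciesParams) -> SimulationResult:
        return simulate(
            params,
            subject,
            dose,
            t_end=config.t_end,
            dt_out=config.dt_out,
            solver=config.solver,
            derived=derive_params(params),
        )

    base = run(p0)
    base_auc = {c: auc(base, c) for c in SENSITIVITY_COMPARTMENTS}

    records = []
    for name in config.parameters:
        if multipliers is not None and name in multipliers:
            mults = np.asarray(multipliers[name], dtype=float)
        else:
            mults = draw_multipliers(
                config.n_samples,
                sigma=config.lognorm_sigma,
                mu=config.lognorm_mu,
                rng=_param_rng(config.seed, name),
            )
        for i, m in enumerate(mults):
            if m == 1.0:
                s_by_comp = {c: 0.0 for c in SENSITIVITY_COMPARTMENTS}
            else:
                try:
                    res = run(perturb_params(p0, name, m))
                    s_by_comp = {
                        c: sensitivity_metric(auc(res, c), base_auc[c])
                        for c in SENSITIVITY_COMPARTMENTS
                    }
                except Exception as exc:  # recorded, not silently dropped
                    warnings.warn(
                        f"perturbed simulation failed for {name} x {m:.4f}: {exc}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    s_by_comp = {c: np.nan for c in SENSITIVITY_COMPARTMENTS}
            for c in SENSITIVITY_COMPARTMENTS:
                records.append(
                    {
                        "parameter": name,
                        "compartment": c,
                        "sample_index": i,
                        "multiplier": m,
                        "S_percent": s_by_comp[c],
                    }
                )

    samples = pd.DataFrame.from_records(records)
    summary = _summarize(samples)
    return SensitivityResult(
        samples=samples, summary=summary, base_auc=base_auc, config=config
    )


def _summarize(samples: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (name, comp), grp in samples.groupby(["parameter", "compartment"], sort=False):
        s = grp["S_percent"]
        ok = s.dropna()
        rows.append(
            {
                "parameter": name,
                "compartment": comp,
                "median_S": ok.median(),
                "q1_S": ok.quantile(0.25),
                "q3_S": ok.quantile(0.75),
                "min_S": ok.min(),
                "max_S": ok.max(),
                "mean_abs_S": ok.abs().mean(),
                "median_abs_S": ok.abs().median(),
                "n": len(s),
                "n_failed": int(s.isna().sum()),
            }
        )
    return pd.DataFrame(rows)
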