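"""Synthetic fixtures: jittered parameter sets, toy organ tables, analytic references.

Everything here is synthetic test scaffolding generated from a seed — used
for robustness tests of the parameter validation, the lumping recipe, and
the AUC machinery (mono-exponential trajectories have a closed-form AUC).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import STATE_NAMES
from .parameters import SPECIES, SpeciesParams, species_params
from .reduction import (
    SIGMA_LOOSE,
    SIGMA_MEDIUM,
    SIGMA_TIGHT,
    OrganEntry,
    write_organ_table,
)

__all__ = [
    "jitter_params",
    "synthetic_organs",
    "mono_exponential_trajectory",
    "generate_fixtures",
]

_ORGAN_NAMES = (
    "lung", "heart", "kidney", "muscle", "skin", "adipose", "thymus",
    "small_intestine", "large_intestine", "spleen", "pancreas", "liver",
    "bone", "other",
)


def jitter_params(
    p: SpeciesParams, rng: np.random.Generator, rel_sd: float = 0.05
) -> SpeciesParams:
    """Multiplicatively jitter every positive parameter by ~rel_sd lognormal noise.

    Fractions and reflection coefficients are re-clamped to [0, 1]; the
    lymph-flow ordering constraints (L < Q) are preserved by re-deriving
    lymph flows from the jittered plasma/bulk flows.
    """
    changes = {}
    for name, value in p.as_dict().items():
        if name == "species_id":
            continue
        v = value * rng.lognormal(0.0, rel_sd)
        if name.startswith("sigma_") or name in ("FR", "FR_B"):
            v = min(max(v, 0.0), 1.0)
        changes[name] = v
    changes["L_T"] = 0.002 * changes["Q_T"]
    changes["L_B"] = changes["Q_B_ECF"] + changes["Q_B_CSF"]
    changes["Q_B"] = max(changes["Q_B"], 2.0 * changes["L_B"])
    return p.replace(**changes)


def synthetic_organs(
    rng: np.random.Generator, n: int = 14, scale: float = 1.0
) -> list[OrganEntry]:
    """A toy non-brain organ table with loose/medium/tight vasculature."""
    sigmas = (SIGMA_LOOSE, SIGMA_MEDIUM, SIGMA_TIGHT)
    organs = []
    for i in range(n):
        name = _ORGAN_NAMES[i % len(_ORGAN_NAMES)]
        if i >= len(_ORGAN_NAMES):
            name = f"{name}_{i}"
        organs.append(
            OrganEntry(
                organ_name=name,
                V_vascular=scale * float(rng.uniform(0.005, 0.5)),
                V_endosomal=scale * float(rng.uniform(1e-4, 0.05)),
                V_interstitial=scale * float(rng.uniform(0.05, 2.0)),
                sigma_vascular=float(rng.choice(sigmas)),
                Q_plasma=scale * float(rng.uniform(1.0, 40.0)),
            )
        )
    return organs


def mono_exponential_trajectory(
    c0: float, k: float, t_end: float, dt: float, compartment: str = "C_plasma"
) -> pd.DataFrame:
    """Trajectory frame with one compartment decaying as c0*exp(-k t).

    Closed-form AUC over [0, T] is c0*(1 - exp(-k T))/k — the analytic
    oracle for trapezoidal-AUC tests.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    df = pd.DataFrame(0.0, index=range(len(t)), columns=list(STATE_NAMES))
    df[compartment] = c0 * np.exp(-k * t)
    df.insert(0, "time_h", t)
    return df


def generate_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the standard fixture files; returns {fixture name: path}.

    Emits jittered species parameter CSVs (synthetic variants of each
    packaged column), a synthetic organ table, and a synthetic
    mono-exponential reference trajectory.  Stable for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    for sp in SPECIES:
        jit = jitter_params(species_params(sp), rng)
        rows = [
            {"parameter": k, "value": v}
            for k, v in jit.as_dict().items()
            if k != "species_id"
        ]
        path = outdir / f"synthetic_params_{sp}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths[f"params_{sp}"] = path

    organ_path = outdir / "synthetic_organ_table.csv"
    write_organ_table(synthetic_organs(rng), organ_path)
    paths["organ_table"] = organ_path

    traj_path = outdir / "synthetic_monoexp_trajectory.csv"
    mono_exponential_trajectory(c0=1e-6, k=0.05, t_end=500.0, dt=0.5).to_csv(
        traj_path, index=False
    )
    paths["reference_trajectory"] = traj_path
    return paths
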