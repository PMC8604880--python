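# brainpbpk

A minimal physiologically-based pharmacokinetic (mPBPK) model of
monoclonal-antibody disposition with mechanistic brain detail, for
scientists supporting preclinical and clinical development of CNS antibody
therapeutics. The central question it addresses: given a dose in mouse,
rat, monkey or human, what antibody exposure is reached in plasma, brain
interstitial fluid (ISF, the presumed site of action) and cerebrospinal
fluid (CSF, the accessible surrogate matrix)?

## Model

The model collapses a whole-body antibody PBPK structure into 16 ODEs —
13 antibody concentrations (plasma; lumped tissue vascular/endosomal/
interstitial; brain vascular; BBB and BCSFB endosomes; ISF; CSF; lymph)
and 3 free-FcRn concentrations — while keeping the mechanisms that matter
for brain disposition:

* convective (paracellular) vascular escape scaled by reflection
  coefficients, with the BBB closed by default (σ_BBB = 1) and the BCSFB
  nearly closed (σ_BCSFB = 0.9973);
* pinocytotic uptake into endosomes, FcRn binding (kon/koff), recycling of
  the bound complex (fractions FR, FR_B) versus transcytosis across the
  barrier, and lysosomal degradation of unbound antibody (k_deg) — the only
  elimination route;
* brain fluid turnover: ISF → CSF bulk flow and glymphatic clearance of
  ISF and CSF to lymph, which drains to plasma.

Secondary transport parameters are derived, not tabulated:
CLUP_T = k_CLUP_T·V_Te, CLUP_B = k_CLUP_B·V_BE split across the barriers by
relative surface area f_BBB = SA_BBB/(SA_BBB+SA_BCSFB), L_T = 0.002·Q_T,
L_B = Q_B_ECF + Q_B_CSF. Exposure is AUC by the trapezoid rule on the
output grid, and the one-at-a-time sensitivity analysis perturbs one
parameter per run with lognormal multipliers (log-sd 0.25) and reports
S = (AUC_perturbed/AUC_base − 1)·100%.

See `docs/methods.md` for the full flux-by-flux description, numerical
choices, and limitations.

## Worked example

```python
import brainpbpk as bp

human = bp.species_params("human")            # packaged parameter column
subject = bp.SubjectSpec(body_weight=70.0, molecular_weight=150_000.0)
result = bp.simulate(human, subject, bp.DoseEvent(time=0.0, dose=10.0),
                     t_end=1000.0, dt_out=1.0)
for comp in ("plasma", "ISF", "CSF"):
    print(comp, bp.auc(result, comp))
```

Running `python examples/simulate_single_dose.py` prints:

```
initial plasma concentration: 1.491e-06 M
AUC 0-1000h, plasma: 3.636e-04 M*h
AUC 0-1000h, ISF   : 3.159e-07 M*h
AUC 0-1000h, CSF   : 1.426e-06 M*h
ISF/plasma exposure ratio: 8.69e-04
```

The initial concentration is the 700 mg bolus (10 mg/kg × 70 kg) in moles
over the 3.13 L plasma volume. The ISF/plasma AUC ratio of ~0.09% is the
hallmark of antibody CNS pharmacology: with the BBB paracellularly closed,
antibody reaches the parenchyma only by FcRn-mediated transcytosis.

Other examples: `ascending_dose_auc.py` (dose linearity at 1–3 mg/kg and
mildly sub-proportional exposure at 100 mg/kg as recycling saturates),
`reduce_organ_table.py` (organ-table lumping), `sensitivity_ranks.py`
(σ_BBB dominating ISF exposure, σ_BCSFB dominating CSF, V_Te leading
plasma).

A thin CLI wraps the same functions:

```sh
brainpbpk params --validate
brainpbpk simulate --species human --dose 10 --t-end 1000 --dt 0.01 --out run/
brainpbpk sensitivity --seed 1 --n 100 --out sens/
```

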