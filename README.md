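# nicotine-pbpk

A whole-body physiologically based pharmacokinetic (PBPK) simulator for
nicotine, built for researchers evaluating systemic nicotine exposure across
delivery systems — intravenous infusion/bolus, traditional smoking, nasal
spray and e-cigarettes — and for regulatory-science use cases such as dose
optimization against target exposures.

## What it implements

* **Perfusion-limited whole-body model.** Eleven perfused tissues plus
  arterial/venous blood; each tissue equilibrates with its emergent venous
  blood via a tissue:plasma partition coefficient,
  `V_i dC_i/dt = Q_i (C_art − C_i·(B:P)/Kp_i)`, with the lung in series
  carrying the cardiac output. The shipped Kp set is a ranked template
  rescaled so the plasma-referenced steady-state volume of distribution is
  exactly `V_ss = (V_plasma + Σ Kp_i·V_i)/BW = 2.70 L/kg`.
* **Dual-mode hepatic elimination.** Either systemic organ clearances
  (CL_H = 40, CL_R = 10 L/h; an 80:20 hepatic:renal split of 50 L/h total,
  applied through a well-stirred intrinsic-clearance formulation so that
  dose/AUC_∞ = CL_H + CL_R exactly), or CYP2A6 Michaelis–Menten kinetics
  scaled from recombinant enzyme data by IVIVE
  (`CLint_u = ISEF·(V_max/K_m)·abundance·MPPGL·liver mass`).
* **Regional respiratory-tract dosing.** Inhaled doses deposit into buccal,
  ET2, BB, bb and alveolar-interstitial regions (20/25/50/5% coarse split,
  alveolar-dominant LRT split), absorb first-order into lung or venous
  blood, ride a mucociliary ladder upward, and the swallowed fraction
  undergoes gut absorption with hepatic first pass.
* **NCA and model qualification.** Cmax/Tmax, trapezoidal AUC, adjusted-R²
  terminal λz and t½, AUC_∞; R ratio (observed/predicted) with the two-fold
  acceptance band, fold error, AFE, RMSE/MAE.
* **Scenario registry.** The nine published clinical verification scenarios
  with observed PK parameters attached, plus sensitivity analysis,
  population spread simulation and synthetic profile fixtures.

See `docs/methods.md` for the model equations, parameter provenance, and
known limitations.

## Worked example

Simulate the first verification scenario — a 30-min intravenous infusion of
0.5 µg/kg/min in a 70-kg subject — and compare with the published clinical
values:

```sh
$ nicotine-pbpk simulate iv_infusion_0.5ugkgmin_30min --out results
iv_infusion_0.5ugkgmin_30min: Cmax 11.2 ng/mL at Tmax 0.5 h; AUC_inf 21 ng*h/mL
```

The infusion delivers 1.05 mg; the peak (11.2 ng/mL) falls exactly at the
end of the infusion (0.5 h), and AUC_∞ = 21.0 ng·h/mL equals dose/total
clearance (1050 µg / 50 L/h). Against the observed clinical values
(Cmax 7.46 ng/mL, AUC_∞ 13.2 ng·h/mL) the R ratios are 0.66 and 0.63 —
inside the two-fold acceptance band. The same can be done in Python:

```python
from nicotine_pbpk import run_scenario, get_scenario

result, params, comparison = run_scenario(get_scenario("iv_infusion_0.5ugkgmin_30min"))
print(params.cmax, params.tmax, params.auc_inf, params.t_half)
# 11.239782503525689 0.5 20.999542663449148 3.155853961663757
print(comparison[["parameter", "observed", "predicted", "r_ratio", "within_two_fold"]])
```

Run all nine verification scenarios at once:

```sh
$ nicotine-pbpk validate --out results
...
30/34 comparisons within two-fold
```

(The comparisons that fall outside the band trace to one source study whose
reported exposures imply a much higher clearance than the model's fixed
50 L/h — see `docs/methods.md`, "Known limitations".)

Other CLI verbs: `nca` (profile CSV → PK parameters), `sensitivity`
(`--param cl_hepatic|cl_total|fu_plasma|hematocrit --values ...`), and
`fixtures` (synthetic mono-/bi-exponential profiles).

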