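# ntcpkit

NTCP-guided radiotherapy plan assessment: dose-volume histograms in,
complication-risk estimates and clinical-goal reports out, plus the paired
cohort statistics for comparing planning techniques.

The package covers the whole-brain-RT analysis workflow:

* **`ntcpkit.dvh`** — differential/cumulative DVH types, conversions, and
  V_x / D_x / D_max / D_min / mean-dose metrics.
* **`ntcpkit.models`** — Poisson dose-response, relative-seriality (RS)
  NTCP (evaluated in log space for the highly parallel `s = 1e-4`
  parameterization), gEUD and LKB probit NTCP, and opt-in EQD2 rescaling.
  RS presets ship for parotid/xerostomia (D50 24.9 Gy, γ 0.26, s 1e-4)
  and lacrimal/dry-eye (D50 63.9 Gy, γ 0.34, s 1e-4).
* **`ntcpkit.goals`** — the ten whole-brain IMRT planning objectives
  (PTV coverage, hippocampal avoidance, lacrimal V15/parotid V20 sparing)
  and per-plan pass/fail reports; a plan is acceptable when ≥ 90% of the
  PTV receives the 30 Gy prescription.
* **`ntcpkit.stats`** — paired two-sided t-tests, Bonferroni control
  (family α 0.05 over the two original-vs-replan comparisons → per-test
  0.025), mean ± SD risk deltas, standardized effect size, and noncentral-t
  power (n = 11, effect 1.1, α 0.025 → ≈ 0.82).
* **`ntcpkit.cohort`** — a seeded synthetic cohort generator producing
  per-patient bilateral-parotid and bilateral-lacrimal DVH triplets
  (original 3D / 3D re-plan / IMRT re-plan) so the full study pipeline runs
  end to end with no external data.
* **`ntcpkit.io` / `ntcpkit.cli`** — a documented DVH CSV dialect, cohort
  and comparison tables, YAML study configs, and a `ntcpkit` command line.

## Command line

```sh
# synthetic end-to-end study (DVHs, per-patient NTCPs, comparison table)
ntcpkit simulate --seed 1 --out-dir study/

# NTCP for DVH files with a shipped RS preset (or explicit parameters)
ntcpkit compute study/cohort_dvhs.csv --preset parotid_xerostomia_rs
ntcpkit compute plan.csv --model lkb --td50 28.4 --m 0.18 --n 1.0

# clinical-goal report for one plan's DVHs
ntcpkit goals plan.csv

# paired plan comparison from a cohort NTCP table
ntcpkit cohort study/cohort_ntcp.csv --out comparison.csv
```

Exit code is 0 on success and 2 on validation errors. All file outputs
report probabilities in percent (one decimal); fractions are used
internally.

### DVH file format

One or more blocks separated by blank lines; `#`-prefixed header lines then
`dose,volume` rows:

```
# structure: parotid
# type: cumulative
# dose_unit: Gy
# volume_unit: relative
dose,volume
0.000,1.000000
20.000,0.500000
40.000,0.000000
```

`volume_unit: cc` is accepted when a `volume_cc` header supplies the total
structure volume; `plan:` and `patient:` labels are optional.

## A note on the parotid risk floor

With the shipped parotid parameterization the Poisson response at 0 Gy is
≈ 0.245, and for a near-parallel organ (s → 0) the RS NTCP of any physical
DVH is bounded below by that value. The nonzero floor is a property of the
published shallow-slope parameter set, not a bug; synthetic-cohort
calibration targets are therefore expressed as bands and orderings rather
than point values.
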