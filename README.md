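# golgiph

Tools for studying how a Golgi-localized electroneutral Cl⁻/HCO₃⁻
exchanger sets the organelle's resting pH through a bicarbonate-mediated
net acid efflux pathway. The package bundles four analysis stages plus the
synthetic-data generators needed to exercise them without any external
dataset:

| module | purpose |
| --- | --- |
| `golgiph.electrochem` | Nernst log-slope, chemical-gradient potentials, and the driving-force decomposition of the pumped proton gradient (61.5 mV H⁺ term, −7 mV K⁺ term, −54 mV Cl⁻ residual ↔ ~0.5 mM luminal Cl⁻). |
| `golgiph.kinetics` | Stiff ODE model of luminal pH: V-ATPase pumping, passive H⁺ leak, Cl⁻ counter-ion channel, 1:1 Cl⁻/HCO₃⁻ exchange gated below pH 5, kinetic bicarbonate buffering (pKa 6.4) and CO₂ escape. Replays permeabilized-cell protocols (SLO / ATP / concanamycin A, bath changes) and finds resting pH. |
| `golgiph.phquant` | Ratiometric probe quantification: 4-parameter logistic calibration and its analytic inverse, mono-exponential initial-rate fits (ΔpH/min), expression-binned regression (600-AU classes over 200–5000 AU), 1-vs-2 component Gaussian-mixture selection by BIC, Student t / ANOVA group comparison with 10–90 percentile box summaries. |
| `golgiph.lectin` | Lectin-microarray fingerprints: replicate aggregation, subtracted fingerprints with per-lectin t-tests and signed fold changes, cross-pair intersection/concordance, reference-sorted heat-map ordering, radar-plot export, and a minimal GenePix GPR reader. |
| `golgiph.synthetic_data` | Seeded generators for calibration tables, single-cell populations (linear expression–pH link or bimodal), pH time courses (closed-form or simulator-driven) and lectin spot tables with planted fold changes. |
| `golgiph.io` / `golgiph.pipeline` / `golgiph.cli` | Schema-validated CSV/TSV IO with provenance sidecars, staged pipeline orchestration, and the `golgiph` command-line interface. |

Two potential conventions are exposed on purpose: `gradient_potential` is
the valence-free chemical-gradient form used by the driving-force
decomposition (it reproduces all the printed signs), while
`nernst_potential_signed` is the textbook valence-signed variant.

Kinetic rate laws are phenomenological (the stoichiometry and pH gating
are constrained; the laws themselves are modelling choices) and their
parameters ship as editable YAML presets (`cos7_control`, `cos7_ae2plus`,
`sw48`) rather than hard-coded constants.

## Command line

```bash
# electrochemical worked example (JSON to stdout)
golgiph electro --ph-lumen 6.0 --ph-cyto 7.0 --k-lumen 107 --k-cyto 140 --cl-cyto 4

# simulate a permeabilized-cell protocol under a preset
golgiph simulate --preset cos7_control --bath cl_hco3 --t-end 30 --out traj.csv

# synthetic data -> calibration -> per-cell pH -> binned regression
golgiph synth calibration --seed 1 --out cal.csv
golgiph synth cells --seed 1 --n-cells 2000 --out cells.csv
golgiph ph cells.csv cal.csv --out cells_ph.csv
golgiph bins cells_ph.csv
golgiph mixture cells_ph.csv --seed 0

# lectin fingerprints
golgiph lectin-compare treated.tsv control.tsv --alpha 0.05 --out sf1.json
golgiph lectin-intersect sf1.json sf2.json

# staged end-to-end run from a config
golgiph run examples/demo.yaml
```

Exit codes: 0 success, 2 input error, 3 numerical failure. Every written
table gets a `<name>.meta.json` sidecar recording version, seed and
parameters.

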