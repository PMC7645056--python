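# radbio

Radiobiological evaluation and paired comparison of radiotherapy treatment
plans from dose–volume histograms (DVHs): DVH metrics, EQD2 fractionation
correction, generalized equivalent uniform dose (gEUD), Lyman–Kutcher–Burman
(LKB) normal-tissue complication probability (NTCP), target
conformity/homogeneity indices, planning-constraint checks, and
repeated-measures cohort statistics. A synthetic-cohort generator emulates a
pancreatic-cancer planning study (24 patients, each planned with IMRT, VMAT
and passive-scattering proton therapy at 50.4 GyE in 28 fractions), so the
entire pipeline runs end-to-end without any clinical data.

The intended users are medical physicists and outcome-modelling researchers
comparing delivery techniques *in silico*.

## The model

For each organ at risk, the cumulative physical-dose DVH is converted
bin-wise to the equivalent dose in 2-Gy fractions with the linear-quadratic
model,

```
EQD2 = D · (d + α/β) / (2 + α/β),     d = D / n_fractions ,
```

reduced to a single effective dose with the generalized equivalent uniform
dose

```
gEUD = ( Σᵢ vᵢ · Dᵢ^(1/n) )ⁿ ,
```

where `vᵢ` is the fractional organ volume in differential bin `i` and `n`
encodes the volume effect (small `n`: serial, max-dose-driven; `n = 1`:
parallel, mean-dose-driven), and mapped through the probit dose response

```
NTCP = Φ( (gEUD − TD50) / (m · TD50) ) ,
```

with published parameter sets `(TD50, m, n)` for six upper-GI endpoints
(gastric bleed, ulceration/perforation, obstruction/perforation, grade ≥3 GI
toxicity) shipped as packaged configuration. Target quality uses the RTOG
homogeneity index `HI = (D2% − D98%)/D50%` and the conformation number
`CN = TV95²/(TV·V95)`. Cohorts are complete blocks (every patient planned
with every modality), analysed per metric with a one-way within-subject
(repeated-measures) ANOVA and Bonferroni-adjusted paired t-tests, plus
per-patient photon-minus-proton NTCP differences (ΔNTCP).

## Worked example

```python
import radbio as rb
from radbio.compare import PlanComparison, cohort_metrics_table

cohort = rb.build_cohort(n_patients=24, seed=2020)          # 72 plans
table = cohort_metrics_table(cohort.plans, cohort.manifest, include_ntcp=True)
results = PlanComparison(table).fit()

results.mean("stomach", "V15", "IMRT")    # 36.25  (% of stomach >= 15 GyE)
results.mean("stomach", "V15", "PSPBT")   # 29.71
results.pairwise_p("stomach", "V15", "PSPBT", "IMRT")   # 1.0e-13
print(results.summary())
```

The summary table starts (abridged):

```
structure    metric              IMRT             VMAT            PSPBT        F        p
stomach      Dmax        52.36±0.63       51.85±0.68       50.23±0.93    80.79 8.87e-16
stomach      V15         36.25±8.16       41.62±8.52       29.71±7.86   396.54 9.91e-30
stomach      V50          0.73±0.55        0.64±0.49        0.22±0.40    14.58 1.24e-05
stomach      V45          4.89±3.94        4.88±3.93        4.93±3.95     5.94  0.00508
```

Reading: the proton archetype irradiates markedly less stomach volume at low
doses (V15: 29.7% vs 36.3/41.6%) and trims the near-maximum dose by ~2 GyE,
while the 35–45 GyE band is essentially technique-independent — so the LKB
chain yields only sub-percentage-point NTCP reductions
(`results.delta_ntcp_frame`), the pattern this kind of plan comparison is
designed to expose.

A command-line interface wraps the same pipeline:

```bash
radbio simulate --n-patients 24 --seed 2020 --out-dir cohort/
radbio metrics  --dvh-dir cohort/ --out metrics.csv
radbio ntcp     --dvh-dir cohort/ --out ntcp.csv
radbio compare  --metrics-csv metrics.csv --out report.csv
radbio run-all  --n-patients 24 --seed 2020 --out-dir results/
```

DVH files use a plain-text dialect (`# structure:`, `# total_volume_cc:`,
`# mode:`, `# volume_unit:`, `# dose_unit:` headers, then `dose,volume`
rows, one file per structure per plan).

## Layout

- `src/radbio/dvh.py` — DVH data model, ASCII I/O, conversions, metrics
- `src/radbio/radiobiology.py` — EQD2, gEUD, LKB NTCP, ΔNTCP
- `src/radbio/plan_metrics.py` — HI, CN, constraint checks, percent reductions
- `src/radbio/synthetic.py` — virtual cohort generator
- `src/radbio/compare.py` — cohort table, RM-ANOVA + Bonferroni model/results
- `src/radbio/cli.py` — `radbio` command-line interface
- `docs/methods.md` — modelling assumptions, calibration and limitations
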