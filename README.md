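# lymphoti

Scoring and outcome analysis for lower-extremity lymphedema (LEL) imaging
and volumetry, aimed at researchers evaluating lymphovenous anastomosis
(LVA) and other microsurgical interventions.

Lymphoscintigraphy — serial whole-body imaging of lymphatic drainage after
a subcutaneous radiotracer injection — is the standard imaging test for
lymphedema, but its qualitative reads (delayed flow, dermal backflow,
invisible nodes) do not by themselves grade severity or predict surgical
benefit. This package implements the composite **transport index**

```
TI = K + D + 0.04·T + N + V
```

where K (transport kinetics), D (dermal backflow), N (ilio-inguinal node
visibility) and V (main-vessel visibility) are ordinal grades in
{0, 3, 5, 9} and T is the node-appearance time in minutes (scored 9 when
nodes never appear, with the time term capped at 9). TI ranges from 0.6
(nodes at 15 min, everything else normal) to 45 (nothing ever visualized).
A shortened two-hour protocol, **TI₁₂₀**, rescores the same study using
only the 15-, 60- and 120-min images; `lymphoti` implements the censoring
rule (forward-snapping of node times, late appearances rescored as not
visualized) and guarantees TI₁₂₀ ≥ TI₂₄₀.

Limb volume is tracked with the **lower-extremity lymphedema index**,
LELI = Σᵢ cᵢ² / BMI over five circumference sites, and post-operative
outcome as the percentage reduction %ΔLELI = 100·(LELIpre − LELIpost)/LELIpre.
A nonparametric analysis battery (Spearman with exact small-sample
permutation p-values, Mann-Whitney, Wilcoxon signed-rank, Kruskal-Wallis,
intra-rater ICC) links TI to stage, pre-operative volume excess and
post-operative outcome. Because the underlying clinical dataset is not
public, a synthetic-cohort generator reproduces the published cohort
structure (component-score marginals, stage split 5/35/5, volume and
outcome distributions) with a calibratable negative TI→%ΔLELI link, so
the entire pipeline is testable end to end.

## Worked example

Two legs of one study, graded from the serial images. The left leg shows
mildly delayed flow (K=3), no dermal backflow (D=0), nodes mildly visible
from the 60-min image (T=60, N=3) and a clearly visible vessel (V=0); the
right leg shows diffuse backflow (D=5) and a hardly visible vessel (V=5)
with clearly visible nodes from 60 min:

```python
from lymphoti import QualitativeRead, transport_index

left  = QualitativeRead(kinetics_score=3, dbf_score=0, node_time=60, node_score=3, vessel_score=0)
right = QualitativeRead(kinetics_score=3, dbf_score=5, node_time=60, node_score=0, vessel_score=5)
print(transport_index(left, 240).value)    # 8.4
print(transport_index(right, 240).value)   # 15.4
```

8.4 = 3 + 0 + 2.4 + 3 + 0 (mild impairment); 15.4 flags the right leg as
the clinically worse limb. Censoring a study whose nodes appear only at
180 min (here with N=5) shows how the shortened window inflates the score:

```python
late = QualitativeRead(kinetics_score=5, dbf_score=5, node_time=180, node_score=5, vessel_score=5)
print(transport_index(late, 240).value)  # 27.2
print(transport_index(late, 120).value)  # 33.0  (nodes now "never seen": +5.8)
```

A full synthetic study from the shell:

```
lymphoti simulate --seed 17 --out-dir cohort/
lymphoti analyze --reads cohort/reads.csv --volumetry cohort/volumetry.csv \
                 --patients cohort/patients.csv --out-dir results/
```

`results/summary.txt` then begins (full precision in `report.json` and the
per-table CSVs):

```
Patients: 45 (stages: {'3': 32, '2': 9, '4': 4})
TI_240: mean 25.2 +/- 10.1 (range 8.6-45.0, n=45)
TI_120: mean 25.3 +/- 10.0 (range 8.6-45.0, n=45)
TI_120 vs TI_240: identical 42, higher 3 (diff mean 1.2, range 1.2-1.2)
Stage-wise TI_240: stage 2: 12.0, stage 3: 27.8, stage 4: 34.0; p=0.000
TI_240 vs pre-op excess: rho=0.348, p=0.019 (n=45)
%dLELI at 3m: mean 8.6 +/- 3.2 (range 2.6-15.3, n=45)
TI_120 vs %dLELI at 6m: rho=-0.347, p=0.019 (n=45)
```

Higher TI (worse lymphatic transport) goes with higher clinical stage,
larger pre-operative volume excess, and smaller post-operative volume
reduction — the negative rho at 3 and 6 months is the predictive signal
of interest.

## Layout

- `src/lymphoti/scoring.py` — reads, TI, censoring, dichotomization
- `src/lymphoti/volumetrics.py` — LELI, %ΔLELI, excess
- `src/lymphoti/stats.py` — exact/asymptotic nonparametric tests, ICC
- `src/lymphoti/synthetic.py` — cohort generator and link calibration
- `src/lymphoti/pipeline.py` — cohort loading, study analysis, reporting
- `src/lymphoti/cli.py` — `lymphoti score|leli|simulate|analyze`
- `docs/methods.md` — models, assumptions and design choices
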