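# xmricc

Sequential XmR control-chart scoring and ICC-based homogeneity monitoring of
monthly expenditure panels.

## The problem

A single payer (a national health insurer, a hospital group, any budget
holder) reimburses hundreds of providers every month and wants two things:

1. **Case-level surveillance** — for each provider, is this month's
   expenditure unusual relative to that provider's own recent history?
2. **System-level assessment** — across all providers, is spending becoming
   more homogeneously controlled over the years, and which providers are
   breaking out right now?

`xmricc` answers both with one pipeline: each provider's monthly series is
scored against a trailing baseline by the XmR (individuals / moving-range)
control-chart method, the signed SD distances are discretized into ordinal
bands, and each calendar year's cases × months band matrix is summarized by
an intraclass correlation coefficient. A bubble table of the two most recent
SD distances per case flags consecutive out-of-control providers.

## The statistics

**XmR scoring.** For month *t* of one case, with trailing window
*x*<sub>t−12</sub>…*x*<sub>t−1</sub>:

- centre line CL = mean of the window,
- sigma = (mean |x<sub>i</sub> − x<sub>i−1</sub>|) / 1.128 (the d₂ constant
  for moving ranges of 2),
- score = (x<sub>t</sub> − CL) / sigma, recorded in bands −4…+4.

**Homogeneity ICC.** A year's n × 12 band matrix is decomposed by two-way
ANOVA without replication; the reported coefficient is the two-way
*consistency*, *average-measures* intraclass correlation

ICC(C,k) = (MS<sub>rows</sub> − MS<sub>error</sub>) / MS<sub>rows</sub>,

numerically identical to Cronbach's α, with the F-based (Feldt) 95% interval.
Reading: months are "raters" of the cases; if they cannot tell the cases
apart (low ICC), every case fluctuates alike around its own centre line —
spending is homogeneously in control. Derived indices follow classical test
theory: SEM = SD<sub>x</sub>·√(1 − r), separation G<sub>p</sub> = √(r/(1−r)),
strata = (4·G<sub>p</sub> + 1)/3 (strata < 2 ⇒ one indistinguishable group).
A Pearson trend over the yearly ICC series tests whether control improves
over time.

**Calibration scenarios.** A Rasch rating-scale generator produces ordinal
panels with known structure (dispersed vs pinned person measures, ramped vs
flat item difficulties) plus a continuous iid N(0,1) null, so the ICC scale
can be anchored: dispersed-measure panels score high, the pinned/null panels
score ≈ 0.

## Worked example

From the printed two-way ANOVA margins of a 421-hospital year
(hospital SS 3044.90 on 420 df, error SS 7643.33 on 4620 df):

```python
>>> from xmricc import AnovaDecomposition, icc_from_anova
>>> a = AnovaDecomposition.from_ss(3044.90, 420, 3915.00, 11, 7643.33, 4620)
>>> e = icc_from_anova(a)
>>> round(e.icc, 3), round(e.f_obs, 2)
(0.772, 4.38)
```

ICC 0.772 (F = 4.38, p < 0.001): the months separate the hospitals easily,
so spending was heterogeneous — some hospitals out of control. A later year
with SS 1488.20/9573.44 gives ICC 0.415: below the 0.5 one-stratum line,
i.e. essentially homogeneous.

End-to-end on simulated data (`python examples/04_bubble_outliers.py`):

```
bubble table for 2000-10 (threshold 2 SD):

case_id     x     y  size    flag
  case2 +4.00 +4.00 +4.00 outlier
  case7 -4.00 -4.00 +4.00 outlier
  case8 +2.94 -0.27 +2.94   watch
  ...
2 of 10 cases show the consecutive two-month effect
```

The two injected 4-sigma two-month excursions — and nothing else — are
flagged as consecutive outliers; a single-month exceedance is only a watch.

The `examples/` scripts each demonstrate one capability (scoring, yearly
ICC + trend, Rasch scenarios, outlier flagging). The same stages are exposed
as a CLI:

```bash
xmricc simulate --scenario panel --n 60 --months 132 --seed 7 --out panel.csv
xmricc score --input panel.csv --out-sd sd.csv --out-bands bands.csv
xmricc icc --sd sd.csv --bands bands.csv --out report.json
xmricc bubble --sd sd.csv --bands bands.csv --month 2009-06 --out bubble.csv
xmricc run --outdir out --seed 7     # full pipeline -> out/report.json
```

## Layout

- `src/xmricc/data_io.py` — wide-CSV matrices, score round-trip, year slicing
- `src/xmricc/xmr.py` — baseline stats, XmR scoring, band discretization
- `src/xmricc/icc.py` — two-way ANOVA, ICC(C,k) + Feldt CI, SEM/strata, trend, χ²
- `src/xmricc/simulate.py` — Rasch rating-scale scenarios, null grids, demo panels
- `src/xmricc/outliers.py` — bubble points and the consecutive-quadrant rule
- `src/xmricc/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
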