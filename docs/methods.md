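# Methods

## Monitoring model

Each monitored case (hospital, provider) contributes a monthly expenditure
series. The scan treats each month as a single observation against a
**trailing, moving baseline** of the previous `baseline_length` months
(default 12 — one seasonal cycle; the scored point itself is excluded from
its window). The XmR individuals-chart estimator is used throughout:
sigma = mean moving range / 1.128. This is the standard d₂-corrected
estimator for subgroups of size two; it reacts to short-range month-to-month
variation and is robust to slow drift, which is exactly the behaviour wanted
when the question is "is this month unusual *for this case*".

The signed score (x − CL)/sigma is discretized two ways:

- **ten_band** (default for monitoring): `sign(sd) · min(4, ceil(|sd|))`,
  codes {−4…−1, +1…+4}. The band edges are open ("<0" / ">0"), so an exact 0
  needs a tie rule; it maps to +1 by default and is configurable
  (`zero_band=-1`). With continuous inputs an exact 0 has measure zero, so
  the choice is inconsequential in practice but must be deterministic.
- **five_band** (for comparisons against 5-category ordinal panels): round
  half away from zero, clip to ±2, shift to {0…4}. Half-away rounding is
  chosen over banker's rounding so the map is monotone and
  sign-symmetric.

**Zero-sigma convention.** A constant baseline window gives sigma = 0. The
scan must not abort on such rows (a flat-lining case is the most in-control
case there is), so an on-centre value scores 0 and an off-centre value is
capped at the band extreme ±4. "On-centre" uses a relative tolerance of
1e-9: the mean of twelve identical floats is not always bit-identical to
them, and without the tolerance a perfectly constant series would score ±4.

Affine invariance holds by construction: rescaling a series x → a·x + b
(a > 0) scales CL and sigma together and leaves every score unchanged, so
cases of very different size are scored on a common gauge.

## Homogeneity assessment

Each complete calendar year of scored months forms an n × 12 matrix of band
codes (ordinal codes treated as numeric responses; a flag switches to the
continuous SD values). Two-way ANOVA **without replication** decomposes it
into case, month and residual components, and the reported coefficient is
the two-way, consistency-type, **average-measures** ICC

    ICC(C,k) = (MS_rows − MS_error) / MS_rows,

identical to Cronbach's α. This flavour — not single-measure, not absolute
agreement — is pinned by its 95% interval: the F-based (Feldt) bounds

    low  = 1 − 1/(F_obs / F(0.975; n−1, (n−1)(k−1)))
    high = 1 − 1/(F_obs · F(0.975; (n−1)(k−1), n−1))

reproduce the published reference bounds for this design (n = 421, k = 13)
to better than ±0.005, which no other common flavour/interval pairing does.
Negative ICCs are reported as computed, never truncated: a value below 0
simply says the months agree less than chance, i.e. the panel is thoroughly
homogeneous. At α → 1 the interval collapses onto the F-median-adjusted
point estimate, which approaches the point estimate as the dfs grow.

Derived indices are classical-test-theory transforms of the reliability r:
SEM = SD_x·√(1−r) with SD_x the standard deviation of the cases' yearly
total scores; separation G_p = √(r/(1−r)); strata = (4·G_p + 1)/3. For
r < 0 the separation indices are evaluated at 0 (no separation information);
r = 1 gives infinite separation and SEM 0. In this application *low*
reliability is the desirable outcome — months that cannot separate cases
mean uniformly controlled spending — so SEM rises and strata falls toward
1/3 as control improves.

The yearly trend is an ordinary Pearson correlation of (year, ICC) with
t = |r|·√(n−2)/√(1−r²) on n−2 df (two-sided p) and a least-squares slope.
A constant series has an undefined r and is flagged degenerate rather than
erroring.

The contingency χ² helper is the standard Pearson statistic without
continuity correction (delegated to `scipy.stats.chi2_contingency`). Note
that the published per-area χ² values this utility accompanies are not
recoverable from the published counts by the standard formula (nor by the
likelihood-ratio variant); the helper implements the textbook statistic and
makes no attempt to imitate those figures.

## Scenario generator

The generator's role is calibration: produce panels whose homogeneity is
known by construction, so ICC readings on real panels have anchors.

- `random_normal`: iid N(0,1) continuous cells — the homogeneous null.
  Its ICC is centred on ≈ 0 (mean ≈ 0.00, SD ≈ 0.077 at 421 × 13 over
  simulated seeds) and the 95% CI covers 0 at the nominal rate.
- Rasch rating-scale scenarios: cell X ∈ {0…4} with
  P(X=j) ∝ exp(Σ_{l≤j}(θ − δ − τ_l)). Person measures θ are either
  standard normal (`increasing`, `decreasing`, `out_of_control`) or pinned
  at 0 (`in_control`); item difficulties δ are linear ramps across the k
  items (+2.0→−1.0, −2.0→+1.0) or flat 0. Thresholds τ default to the
  equally spaced, centred (−1.5, −0.5, 0.5, 1.5); they are exposed as a
  parameter because scenario ICCs are threshold-sensitive. 50/50 mixtures
  stack two scenarios' rows (odd counts give the extra row to the first).
- Two pipelines: **direct** (the sampled categories are the analysis
  matrix) and **xmr** (the sampled categories form a monthly series that is
  itself scanned and five-band recoded — the scan-then-analyze reading).
  Neither is privileged. Under the direct reading, pinned-θ panels are iid
  across cases, which forces ICC ≈ 0; a published in-control reference value
  of ≈ 0.5 for this design cannot arise from that construction, and the
  exact generating pipeline behind it is not recoverable, so scenario point
  ICCs are treated as exploratory rather than as calibration constants.
  What *is* stable, and what the tests assert, is the ordering: dispersed-θ
  panels score far above pinned-θ panels, and mixtures land in between.
- Demo expenditure panels: per-case lognormal base level (σ = 0.4 on the
  log scale, so case sizes span roughly an order of magnitude), geometric
  drift (default 0.3%/month ≈ 4%/year, a typical budget growth cap) and
  multiplicative Gaussian noise (CV 5%, the month-to-month wobble of a
  mid-size provider). Injected shocks are written as
  centre + magnitude·sigma of the case's own trailing window, evaluated
  sequentially, so the scan recovers the stated magnitude exactly and
  flagged ground truth is available for the outlier tests. Shocks require
  nonzero noise (a zero-sigma window cannot express a sigma-scaled shock).

RNG contract: every draw derives from `default_rng([seed, row])`, one
substream per case, so generation is a pure function of (spec, seed) and
adding rows never reshuffles existing ones.

**What the generator does not emulate:** autocorrelated month-to-month
dynamics, seasonality, policy-induced level shifts shared across cases, or
heavy-tailed claim distributions. Passing tests therefore demonstrate the
machinery is correct and calibrated on exchangeable panels, not that real
reimbursement data meet the independence assumption — the ANOVA treats
months as independent judges, which for real series is an approximation
(band-coding weakens, but does not remove, serial correlation).

## Outlier rule

For a chosen month, each case is a point (current SD, previous SD); bubble
size is |current SD| (the magnitude being escalated now). The "rectangular
control area" is the axis-aligned square [−t, t]², t = 2 by default. A point
outside it in the top-right or bottom-left quadrant — both coordinates
strictly beyond t, same sign — is a consecutive out-of-control `outlier`;
any other exceedance (single month, or mixed signs) is a `watch`. Strict
inequality means boundary values do not trigger. Flag counts are monotone
non-increasing in t.

## Numerical and design choices

- SS_error is obtained by subtraction and clipped at 0 to absorb negative
  rounding residue; SS additivity is asserted to ~1e-9 in tests.
- Degenerate inputs never raise mid-pipeline: constant ANOVA matrices,
  zero-variance trend series and zero-sigma baselines all return flagged
  results with NaN statistics (serialized as `null` in reports).
- Report JSON rounds floats to 10 decimals and sorts keys, making reruns
  byte-identical for a given (input, config, seed).
- Problem sizes in tests and the acceptance script: the null-design
  simulation uses 150 seeds at the full 421 × 13 design (a few seconds);
  scenario-ordering checks use 50 seeds at n = 80, where the ordering is
  already near-certain.
- Wide CSV is the only interchange format (cases × months is the natural
  shape of the analysis); month labels are ISO `YYYY-MM`; incomplete rows
  are dropped, not imputed, with the drop count reported.

## Limitations

- ICC flavours other than ICC(C,k), REML/mixed-model ICCs, and
  multiple-testing corrections are out of scope.
- Rasch parameter *estimation* (and separation reliability from an
  estimated model) is not implemented; only response generation is.
- The five-band map and the ten-band zero tie rule are conventions; both are
  documented and the tie rule configurable, but analyses mixing the two
  schemes are not comparable.
- No graphics are produced; bubble and score tables are plot-ready CSVs.
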