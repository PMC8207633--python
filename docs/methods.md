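# Methods

## Model and hypotheses

The package analyses a balanced panel `X_it` (i = 1..N units, t = 1..T
years) of logged, strictly positive observations — in the motivating
application, the natural log of per-capita government health expenditure at
purchasing power parity. The working representation is a time-varying factor
model `X_it = δ_it μ_t`: a single common trend `μ_t` with unit-specific
loadings

```
δ_it = δ_i + σ_i ξ_it / (L(t) t^α),   σ_i > 0,  ξ_it ~ iid N(0,1),  L(t) = log t.
```

Relative convergence of a set of units means their loadings share one limit
`δ`; the decay exponent `α > 0` controls how fast the idiosyncratic part
dies out. Because `μ_t` cancels in ratios, convergence is measured through
the relative transition parameter `h_it = X_it / mean_i X_it` (cross-
sectional mean 1 by construction) and the variance path
`H_t = mean_i (h_it − 1)²`, which tends to 0 exactly under convergence.

The log t regression fits `log(H_1/H_t) − 2 log log t` on `{1, log t}` over
the trimmed window `t = [rT]..T`. Its slope estimates `b = 2α`; convergence
(`b ≥ 0`) is the null of a one-sided t test with an autocorrelation-robust
standard error, rejected when `t_b < −1.65` (5%). The slowly varying
function is fixed at `L(t) = log t`, the form with the best size/power
trade-off in this test family.

## Numerical and procedural choices

- **Trimming.** `start = max(2, floor(rT))` with default `r = 0.3`
  (recommended for T ≤ 50). The floor of 2 guarantees `log log t` is defined
  (the window never contains t = 1) and at least 3 regression points are
  required. For T = 17, r = 0.3 the window is t = 5..17 (13 points).
- **HAC.** The slope variance uses the Bartlett (Newey–West) kernel with lag
  truncation `floor(T^(1/3))` by default (2 for T = 17, 3 for T = 50),
  overridable per call; no small-sample correction. The OLS + HAC step is
  computed by statsmodels; the test suite checks it against an independently
  coded normal-equations + Bartlett-kernel solution to 1e-10 / 1e-8.
- **Degeneracy.** If `H_t = 0` anywhere in the window (all series identical)
  the regressand is undefined; this is reported as the *exact convergence*
  sentinel (`degenerate=True`, decision `"exact"`), never as an arithmetic
  error. The zero test uses a 1e-30 threshold: exact duplicates produce an
  exact floating 0, while genuinely converging noisy panels stay many
  orders of magnitude above it.
- **Decision rule.** Strict inequality for rejection: `t_b = −1.65` passes.

## Club clustering

Steps, each reusing the single regression specification (r, HAC lags,
critical value):

1. **Sort** units decreasingly by final-period value (convergence shows most
   clearly in recent periods). Ties break lexicographically by id, making
   the whole algorithm deterministic. A `last_half_mean` ordering variant is
   available behind a flag.
2. **Core group**: first adjacent pair with `t > −1.65`, extended to the
   group size maximizing the statistic (exhaustive over extensions; a pair at
   the bottom of the ordering stays a bare pair). No passing pair ⇒ no
   convergence subgroups.
3. **Sieve** at `c* = 0` (conservative for samples under 50 units): each
   remaining unit is tested one at a time with the core; admitted candidates
   are jointly tested, and if the joint test fails the club is regrown from
   the core by adding candidates in decreasing order of their one-at-a-time
   statistic, stopping at the first failure. This regrowth fallback is used
   instead of iteratively raising `c*`.
4. **Recurse** on the remainder; a jointly passing remainder forms the last
   club, a singleton or a remainder with no passing pair becomes the
   divergent group.
5. **Merge**: adjacent clubs are tested jointly and merged while the union
   passes, sweeping repeatedly until the classification is stable; the
   divergent group is tested against each club only after club–club merging
   stabilizes, and merges only if the joint test passes.

Reported clubs therefore always re-pass their own test; merging can only
reduce the club count, and merged clubs are unions of consecutive initial
clubs.

## Synthetic data generator

`generate_panel` simulates the factor model directly on the log scale with
known labels. Defaults define the reference study conditions:

- `μ_t`: deterministic linear drift, level 1, +0.02 per period
  (log-income-like growth keeping `X_it = δ_it μ_t` well behaved); a
  random-walk-with-drift variant adds Gaussian innovations of SD
  `0.25 × drift`.
- Loading noise: standard normal, scaled by `σ_i / (L(t) t^α)` with
  `α = 0.5` and `σ_i = 0.05` by default; `L(1)` is replaced by `L(2)`
  because `log 1 = 0` makes the stated scale singular at the first period.
  `σ_i = 0` is allowed and gives the exact noise-free factor structure.
- Divergent units: unit-specific limits plus small per-period drift offsets —
  the minimal structure under the alternative (no shared limit). The
  44 × 17 reference spec (`study_scale_spec`) plants clubs at δ = 1.6, 1.0,
  0.6 (12/14/14 members) and divergent units at δ = 2.8, 0.12, 2.1, 0.35
  with drifts +0.040, −0.004, +0.020, −0.010, chosen so every divergent path
  stays several within-club noise SDs away from every club level over the
  whole sample and no two paths cross.
- Randomness: one seed; per-unit streams are spawned from a SeedSequence so
  a unit's draw does not depend on how many units precede it. Identical spec
  ⇒ bit-identical panel.

What the generator does *not* emulate: structural breaks, cross-sectional
error correlation beyond the common factor, measurement revisions, or any
calibration to observed expenditure series. Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under the stated factor
model, not classification accuracy on real WDI-style data, where separations
are narrower and noise is not iid.

## Simulation scales

The test-suite and acceptance-script problem sizes are the package's
reference conditions: 1000 random panels (N ≤ 20, T ≤ 30) for the
normalization identity; 100 random small panels (N ≤ 10, T ≤ 20) for oracle
agreement; 200 replicates of N = 20, T = 50 single-club panels for size and
of two clubs with a 6-SD limit gap for power; 100 replicates of the 44 × 17
three-club reference spec for partition recovery. At these scales measured
size is far below nominal (under the null `b ≈ 2α = 1 > 0`, so the one-sided
statistic is centred well away from the rejection region), power and
recovery are essentially 1, and the full acceptance run completes in well
under a minute.

## Pipeline determinism and limitations

`run_analysis` writes CSV/JSON reports plus a run log of every resolved
default (HAC lags, start index, c*, ordering and tie rules). Outputs contain
no timestamps, so identical input + config reproduce byte-identical files;
panel CSVs are written with shortest-round-trip float formatting and read
back with round-trip parsing, so write → read is bit-exact.

Known limitations: the test is designed for moderate T (the trimmed window
must keep ≥ 3 points); no pre-testing for structural breaks or unit roots is
offered; smoothing (Hodrick–Prescott trend, λ = 6.25 for annual data) is
off by default and provided only for users following the practice of
filtering before convergence testing; missing cells are a hard error by
design — the method requires a balanced panel and imputation would silently
change the variance path. The club-outcome summary is purely descriptive
(counts, mean, min, max per club); no inferential link between club
membership and outcomes is computed.
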