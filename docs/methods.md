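# Methods

`nitflow` analyses autotrophic nitrogen-removal reactors in which
nitrification and anaerobic ammonium oxidation (anammox) jointly convert
an ammonium feed into nitrate and dinitrogen gas. It couples a
mechanistic reactor simulator to the statistical chain used to relate
microbial community succession to system performance. This note records
the models, the defaults and why they were chosen, and what the
synthetic data do and do not establish.

## Nitrogen mass balance and the performance index

The reactor receives ammonium as the only nitrogen source. On a rate
basis (mg N/day = effluent concentration × flow), the nitrogen missing
from the effluent is attributed to N₂ evasion from anammox:

    N₂-N = NH₄⁺-N(in) − [NH₄⁺-N + NO₂⁻-N + NO₃⁻-N](out)

Anammox produces a small nitrate by-product at a fixed stoichiometry of
0.26 mol NO₃⁻ per 1.02 mol N₂. Because every species is counted as
nitrogen, the molar and nitrogen-mass bases coincide, so the
anammox-derived nitrate is apNO₃⁻-N = N₂-N × 0.26/2.04, and the
remainder npNO₃⁻ = NO₃⁻(out) − apNO₃⁻ is assigned to nitrification.
The performance index is the ratio N₂/npNO₃⁻: high when the feed leaves
as gas, low when it accumulates as nitrate. Biomass assimilation and
heterotrophic denitrification are neglected (autotrophs grow slowly; no
organic carbon is fed).

Degenerate cases: a negative inferred deficit (measurement noise) is
floored at zero with a warning rather than an error; npNO₃⁻ ≤ 10⁻⁹ mg
N/day makes the index undefined and it is emitted as missing, which
downstream smoothing and regression skip. The index is smoothed with a
centered moving average whose window defaults to the hydraulic retention
time (6.25 days), i.e. one reactor turnover.

## The reactor simulator

The simulator is an ideal CSTR (dilution rate D = Q/V = 0.16/day for the
default 4.5 L, 0.72 L/day configuration) with five guilds: AOB
(NH₄⁺→NO₂⁻), NOB (NO₂⁻→NO₃⁻), comammox (NH₄⁺→NO₃⁻), anammox
(NH₄⁺ + 1.32 NO₂⁻ → N₂ + NO₃⁻ at the 0.26:2.04 product ratio, scaled so
nitrogen is conserved exactly), and a nitrogen-neutral heterotroph pool.
Kinetics are Monod in substrate × Monod in dissolved oxygen for the
aerobes; anammox carries a non-competitive oxygen-inhibition factor
K_I/(K_I + DO) with K_I = 0.4 mg O₂/L. Dissolved oxygen is a driven
setpoint trace (default 0.2 mg/L) with optional AR(1) noise, not a
gas-transfer model, because aeration in such reactors is externally
controlled.

Each guild's biomass is split into an attached (biofilm, not washed out)
and a suspended (washed out at D) pool, exchanging at constant
attach/detach rates. Attached growth saturates at a per-guild biofilm
carrying capacity. This term is load-bearing: with oxygen fixed
externally there are only two dynamic resources (NH₄⁺, NO₂⁻), and
without per-guild self-limitation the competition between AOB, NOB,
comammox and anammox generically excludes all but two guilds or falls
into slow limit cycles. A binding space limit per guild pins the biomass
and yields the stable coexisting steady state the analyses assume; it is
also physically reasonable for wall/carrier biofilms. Default capacities
(AOB 5, NOB 3, CMX 30, AMX 9, HET 15 mg/L) were calibrated once so the
steady state reproduces the regime the package models: complete
ammonium and nitrite conversion, nitrate as the major dissolved product
(~90% of it nitrification-derived), N₂/npNO₃⁻ of order 0.5–1, and
Nitrospira-dominated biomass.

Integration is explicit RK4 at dt = 0.02 day with local step-halving
when a step would drive a state negative; clipped negatives larger than
10⁻⁶ of the state magnitude raise an integration error, and more than 12
halvings raise a step-size error. Nitrogen conservation (influent load =
accumulation + effluent export + N₂ evasion) holds to machine precision
by construction and is asserted to 0.1% in the tests; the exported
effluent integral is accumulated inside the integrator, not
approximated afterwards.

`tracer_mean_residence_time` injects a unit pulse into the abiotic
reactor and returns the first temporal moment of the washout curve; for
an ideal CSTR this is V/Q (6.25 days at the default configuration) and
serves as a consistency check on the flow model.

## The packaged succession scenario

`paper_default` encodes the reference operating point (V = 4.5 L, HRT =
6.25 d, 86.4 mg NH₄⁺-N/day, DO ≈ 0.2 mg/L, ~30 °C, pH ≈ 7.6, 56 daily
samples) with a biofilm-homogenizing disturbance at t = 0: the reactor
is first run to its pre-disturbance steady state, then all attached
biomass is resuspended. Three successional stages (days 1–13, 14–34,
35–56) are planted by (i) stage-varying guild fitness multipliers — an
early aerobic bloom while anammox is suppressed, partial recovery in the
middle, full anammox recovery late — and (ii) stage-varying within-guild
taxon weights, with logistic transitions of width 0.5 day at the stage
breaks. The re-attachment (biofilm regrowth) rate after the disturbance
has no field anchor; it is a free parameter (0.15/day for anammox,
0.1/day otherwise) chosen to let the attached pools rebuild over a few
weeks.

The emitted performance index therefore dips during the early stage,
stays low and noisy through the middle, and recovers late — the
qualitative trajectory of a disturbed nitritation-anammox reactor.

Compositionally the three stage archetypes form a *chain*: the early
and late communities differ most, with the middle stage intermediate
(succession drifts to a new state rather than returning to the old one;
function recovers, composition does not). This geometry matters for the
elbow rule below: it makes the two hierarchical splits comparably
valuable, so the within-dispersion curve has its curvature maximum at
k = 3. The rare-taxon tail (90 ASVs, lognormal weights, ~35% of core
mass) drifts across stages as a log-space random walk for the same
reason, and scales up late to echo the late-stage richness rise of
recolonizing reactors.

Counts are Dirichlet-multinomial: expected proportions are the guild-
biomass-weighted taxon weights; the Dirichlet concentration is 900 in
the outer stages and 350 in the middle stage, making the middle stage
genuinely noisier day-to-day. Depth defaults to 42,000 reads/sample so
rarefaction to 30,000 always applies. Effluent concentrations carry 2%
multiplicative measurement noise; DO carries AR(1) noise (sd 0.04 mg/L,
lag-1 correlation 0.8). The scenario definition itself (tail weights,
taxonomy) is frozen under a fixed construction seed; the run seed only
drives noise and sampling, so identical (config, seed) runs are
byte-identical.

What the generator does **not** emulate: sequencing error and chimeras
(counts are drawn from the true composition), copy-number variation
between taxa, compositional effects of extraction/PCR bias, biofilm
spatial structure, pH chemistry, or gas–liquid transfer. Tests that
pass on these data show the statistical machinery is correct and
calibrated under the stated noise model — not that the biological
conclusions transfer to any particular real reactor.

## Community statistics

* **Rarefied diversity** — each sample is subsampled without replacement
  (multivariate hypergeometric) to 30,000 reads, 100 times; richness S,
  Shannon H′ (nats) and Pielou J = H′/ln S are averaged over replicates.
  J is defined as 0 for single-taxon samples (the no-diversity limit of
  the 0/0 form). Composition analyses use a rarefaction-averaged table
  (mean of rarefied tables) so depth differences cannot masquerade as
  community change; rarefaction is unbiased for relative abundances, so
  this equals the raw proportions up to Monte-Carlo noise.
* **Bray–Curtis / NMDS** — BC(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ);
  non-metric MDS (SMACOF with isotonic regression, 50 random restarts by
  default, lowest Kruskal stress-1 kept, k = 3 axes). Zero-dissimilarity
  duplicates are collapsed before embedding and share coordinates after,
  so identical samples are exactly coincident. Axis signs are fixed
  against sample order (equal to day order for time-series tables) so
  repeated runs give reproducible axes.
* **Staging** — Ward linkage on the Bray–Curtis matrix (scipy's `ward`
  on distances, the Ward.D2 convention; applied despite Bray–Curtis
  being non-Euclidean, as is common ecological practice — a caveat, not
  an error, since only the relative merge heights are used). The number
  of stages is chosen by an explicit elbow rule: the k in 2..k_max
  maximizing the second difference W(k−1) − 2W(k) + W(k+1) of total
  within-cluster dispersion, with W computed from squared dissimilarities
  (Σ_{i<j∈c} d²/n_c). Labels are renumbered in order of first temporal
  appearance.
* **Indicator taxa** — for each (taxon, stage), the point-biserial
  association r_pb is the Pearson correlation between the taxon's
  relative abundance and the 0/1 stage membership; p-values come from
  label permutations (999 by default, +1-smoothed, shared across taxa
  for speed). Constant taxa get r = 0, p = 1. No multiple-testing
  correction is applied; consumers should treat the p-values as
  screening values.
* **db-RDA** — the dissimilarity matrix is Gower-centred, principal
  coordinates with non-negative eigenvalues are kept, and their
  projection onto the column space of the centred environmental
  variables gives the constrained inertia fraction; an optional
  permutation test shuffles environment rows. Negative eigenvalues
  (non-Euclideanity) are discarded from both numerator and denominator.

## Trend statistics

Mann–Kendall S = Σ_{i<j} sign(x_j − x_i) with the tie-corrected variance
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 and a continuity-corrected normal
deviate Z = (S∓1)/√Var(S). For n ≤ 10 with no ties the exact null
distribution of S (via Kendall's tau) replaces the normal approximation,
which is poor at small n; with ties at small n the normal approximation
is used. Sen's slope is the median pairwise slope over distinct-day
pairs (the Theil–Sen estimator). The pipeline applies both to the
performance index per successional stage and to the whole series.

## Performance models

All variables are z-scored (interpreting the conventional "unit mean and
variance" standardization phrase as zero mean, unit variance — the only
reading under which coefficients are comparable). Models are OLS with
intercept; AIC is fixed as n·ln(RSS/n) + 2(p+2), counting the intercept
and error variance as parameters — only within-run comparisons are
meaningful, and the constant convention is frozen so results reproduce
bit-for-bit. Best-subset selection enumerates every non-empty subset of
the pool exhaustively (pools are ≤ 15 predictors: 9 in the
environment/diversity/composition table, 10 in the genus table);
exhaustive search is deterministic where stepwise search is
order-dependent. Ties break toward the first-listed subset. The model
table mirrors the standard design: rows for ENV {temperature, pH, DO},
DIV {richness, Shannon, Pielou}, COM {NMDS1–3} and all unions, plus a
univariate-and-multivariate table over the ten most abundant genera.
Significance flags come from coefficient t-tests (two-sided). The index
response is used untransformed; days with a missing index are dropped
listwise.

A caution established while validating the negative controls: with a
fixed 2-point AIC penalty, each irrelevant candidate predictor is
admitted with probability ≈ 0.16 regardless of signal strength, so the
winning model frequently carries one spurious low-coefficient axis on
top of the true drivers. The honest control property — and the one the
tests assert — is that the planted group is contained in the winner and
dominates its coefficients, not that the winner is exactly the planted
set.

## Problem sizes and seeds

Simulations integrate 56-day trajectories at dt = 0.02 day from a
cached pre-disturbance steady state; steady states are declared at a
maximum state derivative below 10⁻⁹. Calibration suites use 10,000 null
series (trend test), 10,000 null taxa (indicator uniformity), 200
scenario seeds (stage recovery), 200 selection runs (AIC recovery) and
500 runs (Sen's slope recovery). All randomness derives from explicit
integer seeds; the pipeline derives per-step sub-seeds from its single
seed via `numpy` SeedSequence and logs them.

## Known limitations

* The guild model is a caricature: five lumped guilds, shared
  half-saturation for the two anammox substrates, no nitrifier
  denitrification, no N₂O pathway.
* The biofilm capacity term stabilizes coexistence but removes genuine
  competitive-exclusion dynamics; scenarios plant succession through
  fitness multipliers rather than emergent ecology.
* Bray–Curtis + Ward.D2 and NMDS inherit the usual compositional-data
  caveats; no phylogenetic metrics are provided.
* The empirical regression tables of the study system this package
  emulates are not reproducible here because the underlying chemistry
  measurements are not public; the pipeline reproduces the table
  *structure* and is validated on synthetic data only.
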