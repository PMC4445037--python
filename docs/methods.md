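# Methods

## The problem

Celecoxib for knee or hip osteoarthritis is prescribed at two official
dosage regimens — 200 mg once daily (QD) and 100 mg twice daily (BID) — and
the randomized evidence comparing them head-to-head is thin: in the
published 24-RCT network only two three-arm trials compare the regimens
directly, while 19 trials compare 200 mg QD with placebo and 7 compare
100 mg BID with placebo. A network meta-analysis (NMA) combines the direct
head-to-head evidence with the indirect evidence that flows through the
placebo node, yielding a coherent estimate for every pairwise contrast.

This package implements the complete evidence-synthesis machinery for that
three-node network: effect sizes, a Bayesian random-effects NMA with its
own MCMC sampler, treatment ranking, direct-vs-indirect consistency checks,
classical pairwise meta-analysis, and a synthetic trial-network generator
with known truth. The raw arm-level outcome data of the included trials
were never deposited, so the published posterior estimates are not
reproduction targets; instead the machinery is validated against closed
forms, hand-computed examples, and simulated networks whose truth is known.

## Effect sizes

Continuous outcomes (pain or function severity scores, arbitrary units) are
standardized per trial as Hedges' g: with pooled SD
s_p² = ((n_x−1)s_x² + (n_y−1)s_y²)/(n_x+n_y−2), the raw SMD
d = (x̄−ȳ)/s_p is shrunk by J = 1 − 3/(4(n_x+n_y−2)−1), and
Var(g) = (n_x+n_y)/(n_x n_y) + g²/(2(n_x+n_y)). The bias correction is
negligible at the arm sizes of this network (≥ 117 per arm) but costs
nothing. Negative g favors the first arm (outcomes are severities).

Binary adverse-event outcomes are contrasted as log odds ratios from the
2×2 table with variance 1/a + 1/b + 1/c + 1/d; when any cell is zero, 0.5
is added to all four cells (Haldane–Anscombe). Trials with zero (or all)
events in both arms remain finite after correction but are flagged and
excluded from classical pooling; the Bayesian binomial model needs no
correction and uses the raw counts.

When a study reports several scales for the same outcome, the scale ranked
highest in an explicit hierarchy is analyzed (pain: VAS walking pain,
WOMAC pain, VAS global, other; function: WOMAC function, WOMAC total,
Lequesne, other). The hierarchies ship as an editable JSON config because
the convention is a named rule, not an algorithm.

## The Bayesian NMA model

Treatments enter through basic parameters d_k, the effect of treatment k
versus the reference (placebo) on the linear-predictor scale, with
d_ref ≡ 0; every other contrast is d_X − d_Y (the consistency relation).
Trial-specific effects δ_ik are exchangeable around these means with a
single between-trial SD τ shared by all comparisons (homogeneous-variance
assumption). In a three-arm trial the two deltas are jointly normal with
covariance τ²/2 — equivalently the sequential conditional construction in
which arm k has conditional variance τ²·k/(2(k−1)).

* **Binary outcomes** use the arm-level binomial likelihood:
  r_ik ~ Binomial(n_ik, p_ik), logit(p_ik) = μ_i + δ_ik, δ = 0 on the
  trial's baseline arm. Parameters: 24 baselines μ, one δ per non-baseline
  arm, 2 basic parameters, τ — for the full geometry, 50 binomial data
  points.
* **Continuous outcomes** use trial-level contrasts: y_ik = Hedges' g of
  arm k against the trial baseline, y_ik ~ N(δ_ik, v_ik), with covariance
  1/n_baseline between two contrasts sharing a baseline arm (the baseline
  arm's share of the standardized variance). The δ are marginalized
  analytically, so the sampler only walks (d, τ) — 26 contrast data points
  for the full geometry.

Priors are vague Normal(0, 10000) on all location parameters (d, μ) and
uniform on τ: U(0, 2) on the SMD scale, U(0, 5) on the log-odds scale —
bounds far above any plausible heterogeneity for standardized or log-odds
effects. τ can be pinned (`tau_fixed`) for analytic checks; pinning it at
zero reduces the continuous model to its conjugate-normal closed form,
which is how the sampler is validated against an exact oracle.

## Sampling

A self-contained component/block random-walk Metropolis-within-Gibbs
sampler:

* μ updates are proposed for all trials at once and accepted per trial
  (valid because the μ_i are conditionally independent);
* δ updates are proposed as one block per trial;
* each d_k and log τ are scalar random-walk updates (uniform prior on τ
  plus the log-scale Jacobian).

Proposal scales adapt in batches of 50 iterations toward ≈ 35% acceptance
during burn-in only; adaptation is frozen afterwards, so the retained chain
satisfies detailed balance. Three chains run by default with dispersed
starts: d offset by (c−1)·0.5, τ at {0.05, 0.2, 0.5}, μ/δ at empirical
logits. Per-chain seeds are base_seed + chain index; identical (model,
config) inputs reproduce draws bit-identically. Default settings follow
the common convention of 3 chains × 50 000 iterations with the first
10 000 discarded; the tests and analysis drivers use 3 × 6 000–20 000,
which this small network mixes well within (all split-chain R-hat < 1.05,
checked via arviz).

Posterior summaries are the median and the 2.5th/97.5th percentiles
(95% credible interval), exponentiated for odds ratios; "significant"
means the CrI excludes 0 (SMD) or 1 (OR).

## Residual deviance

Model fit is assessed by the posterior mean residual deviance D_res, which
should be close to the number of data points for an adequate fit. Binomial
contributions are 2[r ln(r/r̂) + (n−r) ln((n−r)/(n−r̂))] with r̂ = n·p̂ and
0·ln 0 ≡ 0, averaged over draws, one per arm. Continuous contributions are
the per-trial quadratic form (y−δ)ᵀV⁻¹(y−δ); because the continuous sampler
marginalizes δ, the deviance is Rao-Blackwellized — δ is integrated against
its exact Gaussian conditional given each (d, τ) draw, which equals the
average over δ draws without extra Monte-Carlo noise. Under the contrast
likelihood the expected contribution of a well-fitted trial equals its
number of contrasts, so `n_datapoints` counts contrasts for continuous
models (26 for the full geometry) and arms for binary models (50). A
well-specified simulated binary network gives D_res/n ≈ 0.95–1.0; pinning
τ ≈ 0 on strongly heterogeneous data inflates D_res several-fold.

## Ranking

Each retained draw orders the treatments by effect (reference included at
0; direction stated per outcome — lower SMD or lower OR is better). Ties
are broken uniformly at random from a dedicated seeded stream. Tallying
across draws gives the rank-probability matrix (doubly stochastic by
construction); SUCRA_t = 100·Σ_{j≤T−1} cum_{t,j}/(T−1) is 100% for a
certain-best treatment, 0% for certain-worst, and averages exactly 50%
over treatments for any valid rank matrix. P(best) and SUCRA are always
reported side by side: the two summaries answer different questions and
cumulative-ranking percentages are easily misread as rank-1 probabilities.

## Classical pairwise meta-analysis and bias screening

Direct comparisons are pooled with DerSimonian–Laird: Q = Σw_i(y_i−ȳ_FE)²
with fixed-effect weights w_i = 1/v_i, τ²_DL = max(0, (Q−(k−1))/(Σw −
Σw²/Σw)), random-effects weights 1/(v_i+τ²), Wald 1.96 CIs (no
Knapp–Hartung — matching the era's convention), I² = max(0, 100(Q−df)/Q),
and the χ² heterogeneity p-value. The implementation is cross-checked to
1e-9 against statsmodels' `combine_effects`. Multi-arm trials contribute
to each pairwise comparison independently in classical pooling (no
shared-arm adjustment), mirroring common practice; the Bayesian model
handles that correlation properly.

Publication bias is screened with the Begg–Mazumdar rank correlation
between standardized fixed-effect deviates u_i = (y_i−ȳ_FE)/√(v_i−1/Σw)
and the variances, using Kendall's tau-b and the normal approximation of
Kendall's S with continuity and tie corrections. With fewer than three
studies the test is undefined and p = 1 is returned with a flag. Under a
simulated null the test is mildly conservative (≈ 3–4% rejections at
nominal 5%), a known property of the corrected rank statistic; the test
suite asserts that the nominal level is held, not exact uniformity.

## Loop inconsistency

The single closed loop (QD–BID–placebo) is checked by the Bucher method:
the indirect estimate is the difference of the two pooled vs-placebo
estimates with variances adding, and the discrepancy with the pooled
direct estimate gives z = Δ/√(v_d+v_i). On the OR scale exp|Δ| is the
ratio of odds ratios, reported ≥ 1 by orientation, with inconsistency
significant when the oriented CI excludes the null (|z| > 1.96). Direct
and indirect inputs come from DL pooling of the edge subsets, keeping the
check independent of the MCMC. Under a consistent simulated null the
significance rate is ≈ 5% (checked at 2000 replicates).

## Synthetic data generator

The generator draws exactly from the model the NMA assumes — this is
deliberate: it makes parameter recovery, interval coverage, and deviance
calibration interpretable as tests of the machinery, not of model
robustness. Per trial, δ is drawn jointly normal around the consistency
means with SD τ (covariance τ²/2 within three-arm trials). Continuous arms
then sample an observed mean from Normal(μ_arm, σ²/n) and an observed SD
from the scaled-χ² sampling law (σ = 20 on a 0–100 severity score,
baseline mean 60), so estimated effect sizes carry realistic sampling
noise. Binary arms draw a per-trial control logit from
Normal(logit 0.25, 0.3) — emulating varying control-arm AE rates — and
events from the implied binomial.

The default configuration is the published geometry: 2 three-arm trials,
5 BID–placebo, 17 QD–placebo, arm sizes uniform on 117–481 (the printed
range), truth at the published posterior medians (SMD −0.38 QD / −0.42 BID
with τ = 0.15; GI-AE log-ORs ln 1.19 / ln 1.28 with τ = 0.1, consistent
with the I² = 0% reported on those edges). What the generator does *not* emulate —
outcome-scale selection, missingness, duration/follow-up differences,
non-normal scores, correlated adverse events — bounds what passing tests
show: the machinery is correct under its own assumptions; nothing here
validates those assumptions on real trials.

## Numerical choices and degenerate inputs

* Zero pooled SD, events > n, sd ≤ 0, duplicate (study, treatment) rows and
  disconnected networks are rejected with row-naming validation errors.
* k = 1 pooling returns the single estimate with τ² = Q = I² = 0; Q ≤ df
  truncates τ² to 0 and reproduces the fixed-effect answer exactly.
* Double-zero binary trials are flagged and dropped from classical pooling.
* Posterior ties in ranking are broken by a seeded RNG substream, so
  results are reproducible yet unbiased.
* The τ = 0 branch of the continuous deviance avoids the singular prior by
  setting δ to its consistency mean.
* The Lisse 2001 row of the packaged trial table is stored exactly as
  printed (a pooled report of three RCTs, `combined_from = 3`); counting
  operations expand the flag, which reconciles the printed table with the
  published totals (24 RCTs, 50 arms, 8 knee-or-hip trials).

## Known limitations

* The binary sampler's random-walk d-updates mix more slowly than a
  gradient or conjugate sampler; the default draw counts compensate for
  this three-node network but would need raising for larger networks.
* Continuous modeling is contrast-based; arm-level continuous likelihoods
  (and hence the arm-count deviance convention some engines report) are not
  implemented.
* Node-splitting beyond the single Bucher loop, meta-regression, and
  fixed-effect NMA variants are out of scope.
* Published posterior estimates for the real outcome data cannot be
  reproduced here because the arm-level outcome data were never published;
  the published medians enter only as generator truth and as inputs to
  consistency arithmetic.
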