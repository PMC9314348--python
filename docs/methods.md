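# Methods

This note documents the statistical model implemented in `kinact`, its
tunable parameters, the numerical choices made where the procedure left room
for interpretation, what the synthetic-data generator does and does not
emulate, and known limitations.

## Model and assumptions

The core hypothesis is that the more active a kinase is, the more of its
substrates appear in a phosphoproteomic experiment. Evidence is strictly
binary (a site was observed or it was not): relative quantification is never
used inside the activity statistic, because MS intensities are not
comparable across peptides. Tyrosine (Y) and serine/threonine (ST) sites are
disjoint universes processed independently — separate backgrounds, networks,
random draws and scores.

The pipeline composes four stages:

1. **Pruning** a dense weighted kinase–substrate prediction graph into an
   ensemble of binary networks under three constraints: fixed substrate
   count per kinase, a cap on each substrate's kinase degree, and a fixed
   per-kinase study-bias composition mirroring the whole phosphoproteome.
   The fixed substrate count makes scores comparable across kinases; the
   degree cap prevents hub substrates from providing evidence for many
   kinases at once; the bias quota prevents well-studied sites from
   dominating any kinase's substrate set.
2. **Hypergeometric enrichment** P(X ≥ k) per (kinase, network), with
   k = observed substrates, K = the kinase's substrate count, n = evidence
   size within the background, N = background size for the residue class.
   k = 0 returns exactly 1.
3. **Mann–Whitney aggregation** of the ensemble's real p-values against
   those of 150 study-bias-class-matched random experiments (one-sided:
   real stochastically smaller). The score is −log₁₀ of the test p-value
   and saturates at the resolution of the U statistic; no artificial cap is
   applied on top of that intrinsic limit.
4. **Empirical FPR**: 100 decoy iterations each treat one random experiment
   as real against the remaining 149; FPR = fraction of decoy p-values at
   least as significant (≤, the conservative choice; configurable to strict
   <) as the real one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| substrates_per_kinase | 2000 (Y) / 2500 (ST) | finishing substrate count per kinase |
| max_kinases_per_substrate | 10 (Y) / 20 (ST) | substrate degree cap |
| n_networks | 50 | ensemble size |
| bias bins (pruning) | exact compendia counts 0..5 | per-kinase quota bins |
| bias classes (resampling) | 0 / 1–2 / 3–5 → low/medium/high | random-draw stratification |
| n_random | 150 | random experiments per condition |
| n_decoys | 100 | decoy iterations for the FPR |
| minimum evidence (warning) | 50 (Y) / 1000 (ST) sites | below this, power is typically poor |

Pruning quotas use exact compendia counts while random resampling uses the
three coarse classes: the 4- and 5-compendia strata are tiny, and sampling
them as separate strata would make "random" draws nearly deterministic in
those strata.

## Numerical and design choices

- **Quota integerization**: per-bin quotas are proportional shares of the
  substrate limit, rounded by largest remainder (ties toward less-studied
  bins); bins with no background sites receive nothing. Quotas may
  legitimately be zero for tiny bins.
- **Draw schedule**: kinases are visited round-robin, one edge per visit,
  filling the bin with the largest remaining quota (ties toward
  less-studied). This prevents early kinases from exhausting shared
  substrates under the degree cap.
- **Weighted sampling**: sequential weighted draws without replacement are
  realised by the exponential-race construction — each candidate edge gets
  an independent key Exp(1)/weight and edges are consumed in ascending key
  order. Conditioned on the currently eligible candidate set, the minimum
  key is attained by each edge with probability proportional to its weight,
  so the scheme is distributionally identical to naive sequential draws but
  needs one sort per kinase/bin instead of one cumulative sum per draw.
- **Quota infeasibility**: if a kinase's candidates in a bin run out, the
  deficit is borrowed by the nearest bin with remaining candidates
  (preferring less-studied), with a logged warning; a hard error is raised
  only when the kinase's total candidate pool cannot cover its limit. The
  degree cap is enforced per network, each network being an independent
  alternate representation.
- **Ensemble seeding**: member i is pruned with seed base+i; provenance
  (seed, config hash) is stored with each network, and identical inputs
  reproduce ensembles bit-for-bit.
- **Mann–Whitney implementation**: exact permutation enumeration (valid
  under ties) when both sides have ≤ 8 values; otherwise the normal
  approximation with tie and continuity corrections. Real use compares ~50
  network p-values against 150 × 50 pooled random values, far inside the
  asymptotic regime. Pooling all draws × networks is the default; a
  per-draw-median option exists.
- **Degenerate evidence**: kinases with zero observed substrates in every
  network still receive a score (all real p = 1 → p ≥ 0.5), never NA.
  Evidence sites absent from the reference background are dropped from *n*
  and logged, so a background class shortfall cannot arise by construction.
- **Mapping**: duplicate rows for one site are collapsed keeping the
  maximum-magnitude value per quantification column (preserving thresholded
  evidence); missing quantification means "not observed", never imputed.
  The 50/1000 minimum-evidence sizes are warnings, not errors. Position
  renumbering against a different reference isoform is out of scope: sites
  that fail to match the reference are excluded and logged.
- **Benchmarking**: rank hits use competition (min-rank) ties, so a tie
  group straddling the top-k boundary counts as a hit. Removal counts use
  round-half-to-even. "FDR" per loss-curve point means each algorithm's own
  significance notion (empirical FPR for the ensemble method, BH-adjusted p
  for KSEA). Tolerable loss reads the *first* loss of the 3-of-5 majority;
  transient recoveries at higher loss do not extend it. Sensitivity areas
  are trapezoidal over 0–50% with the 0% point set to the full-data FDR.
- **KSEA**: δ is the population (ddof = 0) standard deviation; missing
  fold changes are excluded from both s̄ and p̄; the right-tailed test uses
  signed z (a two-sided option exists). **KARP**: intensities are used as
  given; no internal normalization.

## Synthetic data

The generator emulates the statistical structure the algorithm assumes: a
background phosphoproteome with a heavy-tailed study-bias profile (default
55% of sites in no compendium, 3% in all five), and a dense weighted graph
in which each kinase has a high-weight "core" of preferred substrates
(weight ≈ 0.9) over a low-weight background (≈ 0.05), with enough candidates
per bias bin to satisfy the default quotas — feasibility is checked at
generation time. Experiments optionally plant a signal: a chosen fraction of
evidence sites drawn from one kinase's top-weight substrates. Quantitative
columns add Gaussian log2 fold changes (σ = 1) with a planted mean shift
(default 1) on member sites.

The generator does *not* emulate peptide-level MS artifacts (missed
cleavage, ionization efficiency, peptide-specific losses), isoform
ambiguity, or the correlated substrate structure of real kinase families.
Passing tests therefore demonstrate the statistical machinery — constraint
satisfaction, calibration, recovery under the generator's planted model —
not predictive accuracy on real phosphoproteomes, which depends on the
quality of the input prediction graph.

## Test-problem sizing

The statistical acceptance tests and `scripts/acceptance.py` run on a
deliberately scaled-down system chosen to exercise every code path with
non-trivial statistics: 20 kinases over a 5000-site background, 500
substrates per kinase, ensembles of 10 networks (50 for the pure constraint
checks), with the inference-stage settings kept at their defaults (150
random experiments, 100 decoys). Null calibration aggregates 200
(kinase, run) pairs; recovery uses planted experiments of 100 sites at
enrichment fraction 0.3.

## Known limitations

- The prediction graph is consumed as given; generating or re-weighting
  predictions is out of scope, and inference quality is bounded by the
  input graph.
- The score saturates (the "statistical limit"), so strong conditions can
  be indistinguishable at the top of the scale; quantile normalization of
  profile matrices partially mitigates this for cross-sample comparison.
- FPR granularity is 1/n_decoys; an FPR of 0.0 means "< 1/100" at the
  default setting.
- Mapping assumes the experiment's coordinates already refer to the
  reference accession's numbering; no sequence-level validation is
  attempted.
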