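# Methods

## Overview

`craave` analyzes pooled CRISPR screens read out from AAV episomes
recovered from mouse brain. The unit of observation is the sgRNA
(identified by its protospacer); the unit of inference is the gene group
(a gene, or one of its transcription-start-site guide sets P1/P2, which
are always scored independently). Control samples are sequencing runs of
the injected AAV library; treatment samples are per-mouse episome
recoveries.

## Guide counting

Reads are assigned by **exact string matching** of library protospacers —
deliberately no mismatch tolerance, since amplicon sequencing of a defined
cassette gives no alignment evidence to adjudicate mismatches. The default
`scan` policy hashes all protospacers and slides a window across each
read, so the amplicon layout need not be declared; `fixed(start)` mode
checks one offset and is faster. A read matching two or more distinct
protospacers is counted `ambiguous` and never assigned (exact matching
provides no tie-break). Reads are matched forward-strand only by default
(single-primer amplicon orientation); a reverse-complement option exists.
Read accounting always satisfies assigned + unassigned + ambiguous =
reads seen.

## Normalization and filtering

Counts are normalized by **median-of-ratios**: per-sample size factor =
median over reference guides (nonzero in every sample) of the guide's
count divided by its geometric mean across samples. Size factors are
rescaled to geometric mean 1; this makes normalization idempotent. A
consequence worth knowing: multiplying one sample's raw counts by c
rescales the whole normalized matrix by c^(1/K) (K samples) because the
per-guide geometric-mean reference shifts — all between-sample ratios,
and hence all downstream statistics of interest, are unaffected.

Guides with **fewer than 100 raw reads summed across control samples**
are excluded before any statistic is computed (a guide barely present in
the virus prep cannot be scored for depletion). The threshold is a
parameter (`filter_threshold`, default 100); the rule is `sum >= 100`
retains.

## Per-sgRNA negative-binomial test

Per retained guide, the control mean mⱼ and sample variance vⱼ of the
normalized control columns feed a weighted least-squares fit of
ln v = a + b·ln m. Weights default to the control means (the log-variance
of a larger-mean guide is estimated more precisely); an unweighted fit is
available. Guides with zero sample variance are excluded from the fit but
still receive predicted variances.

The test parameterizes a negative binomial with mean mⱼ and variance
σ²ⱼ = max(exp(a + b·ln mⱼ), mⱼ·(1 + 10⁻⁶)) — the floor keeps the NB
defined and continuous with the Poisson limit when the fitted trend dips
below the mean. The observed value is the normalized treatment abundance
(cohort mode: mean over mice; per-mouse mode: one column), rounded
half-up onto the integer support. p_under = P(X ≤ k) and p_over =
P(X ≥ k); both tails include the observed point, so both lie in (0, 1].

With a single control sample the variance is undefined; the code falls
back to variance = mean (Poisson) and the caller is warned through the
error message requiring the explicit fallback.

The phenotype φⱼ = log₂((treatment mean + 0.5)/(control mean + 0.5)); the
pseudocount keeps φ finite for fully depleted guides and is never applied
to the test itself.

## Gene aggregation (geopagg) and the amalgam null

Underabundance and overabundance are processed in parallel. Guide
p-values are BH-corrected **across the full retained guide family,
nontargeting controls included** (they are part of the same multiple
testing family and their FDRs feed the null). Per group, sorted FDRs get
Drop-First weights — 0.5 for every guide whose FDR equals the group
minimum, 1.0 otherwise. The literal set condition means ties at the
minimum are all down-weighted; a `single_first` mode halves only one
guide, for users who read "the first sgRNA" strictly. q, φᵢ and
γᵢ = φᵢ·(−log₁₀ q) follow the formulas in the README.

**Amalgams.** The number of amalgam pseudo-genes defaults to the number
of real gene groups: the membership-size multiset of the real library is
used verbatim (permuted) so the null matches the gene-size distribution
exactly, and the NTC pool is reused across amalgams (only ~250 NTCs exist
against ~1,000–2,300 groups; distinctness is enforced within each
amalgam). The amalgam seed is an explicit parameter recorded in output
metadata — δ values are reproducible only given it.

**Empirical FDR.** Genes and amalgams are ranked by γ (ascending for
depletion, descending for enrichment; ties broken by q then by key for
determinism). δᵢ = max(cᵢ/i, qᵢ) with cᵢ the running amalgam count, then
a cumulative-max pass enforces monotonicity. The qᵢ inside δ is the
per-direction q at that rank. Amalgams are dropped from reported tables
after serving as the null. The reported direction per gene is the one
with smaller δ (tie → smaller q → depleted); hit = δ < 0.1. Hits whose
group has exactly one guide FDR below the hit threshold are flagged
`one_guide_driven`.

## Cohort analyses

Per-mouse screens rerun the whole pipeline with one treatment column
against all controls, reusing the cohort's filter and amalgam seed, and
tabulate a genes × mice hit-indicator matrix.

The bootstrap analysis subsamples mice **without replacement** (the
field's name "bootstrap" notwithstanding) at each requested cohort size,
reruns the screen per draw, and reports the fraction of the full-cohort
hit set recovered. Amalgam seeds are spawned per resample from the master
seed so draws are independent but reproducible — except the identity draw
(size = full cohort), which reuses the full-cohort amalgam seed so that
it reproduces the reference screen exactly and overlap is 1 by
construction. Per-gene recovery fractions are column means of the
indicator matrices and therefore consistent with the per-draw overlaps.

## Synthetic screens

The simulator states a world and samples from it:

| parameter | default | why |
|---|---|---|
| n_genes × guides_per_gene + n_ntc | 1000×5 + 250 | desk-scale version of a ~12k-guide CRISPRi library with ~250 NTCs |
| fraction_essential, effect_size_lfc | 0.02, −2 | a small set of strongly depleted genes, the regime screens are powered for |
| active_guides_per_essential_gene | 4 of 5 | variable guide efficacy; one inert guide per essential gene |
| n_mice, neurons_per_mouse, moi_mean | 10, 5×10⁵, 2 | whole-brain neuronal screens at MOI "1–3" |
| cre_fraction | 1.0 | broad Cre; lower values model restricted populations |
| reads_per_sample | 5×10⁶ | ~950 reads/guide |
| input_abundance_sigma | 0.5 | lognormal spread typical of plasmid-pool cloning |
| nb_dispersion (a, b) | (0, 1) | plain multinomial reads; episome sampling already dominates overdispersion. Setting a > 0 adds gamma–Poisson noise with var = eᵃ·meanᵇ |
| n_controls | 2 | minimum for a defined mean-variance fit |

Generative model per mouse: each neuron receives Poisson(moi_mean) guide
copies drawn by input frequency; each copy survives with probability
min(1, 2^LFC) and a neuron dies if **any** copy draws death (so
co-infected neurons couple guide phenotypes, as expected at MOI > 1);
surviving Cre-positive neurons contribute all their copies as episomes;
reads are sampled from episome frequencies.

What the simulator does **not** emulate: regional tropism heterogeneity,
spatial structure, PCR jackpotting, index hopping, guide-level off-target
effects, and any quantitative link between LFC and neuron death beyond
the thinning stand-in. A green recovery test therefore establishes that
the statistics recover the stated generative signal at the stated
coverage — not that the effect-size calibration matches any particular
biological system.

## Numerical choices

- Guide FDRs are clipped to machine-tiny before logs (q = 0 is
  impossible under BH but guarded anyway).
- Half-up rounding (`floor(x + 0.5)`) onto the NB support: deterministic,
  no banker's rounding surprises.
- All rankings use stable mergesort with explicit tie-break keys, so
  outputs are byte-identical across reruns with equal seeds.
- Seeds: every stochastic stage takes an explicit seed; compound
  procedures (bootstrap) spawn child seeds from one master generator.
- Garwood Poisson intervals via chi-square quantiles; the
  numerator/denominator CI for the inverted-handle fraction combines two
  independent Poisson intervals conservatively and is not capped at 1.

## Known limitations

- Exact parity with external exact-match counters on real reads is not
  guaranteed (constant-prefix trimming behavior is amplicon-specific);
  scan mode sidesteps the layout question.
- The WOLS weighting scheme and the treatment summarization (mean vs
  per-mouse) are configuration choices, not uniquely determined by the
  method description this implements.
- Cohort-mode testing of the treatment **mean** against a single-sample
  NB is conservative (the mean of n mice has smaller variance than one
  sample); per-mouse mode is the anti-conservative extreme. The empirical
  amalgam FDR largely absorbs either miscalibration at the gene level.
- With ~250 NTCs and thousands of amalgams, amalgam genes share guides;
  the null's effective resolution is bounded by the NTC pool size.
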