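# craave

Analysis toolkit for **pooled in vivo CRISPR screens read out from AAV
episomes** — the screening design in which a guide library is delivered to
the mouse brain by AAV, episomal sgRNA cassettes are PCR-recovered from a
Cre-defined neuronal population, and each gene's essentiality is inferred
from the depletion of its guides relative to the injected AAV input pool.

It is written for screen analysts and method developers who need the whole
stack runnable at desk scale: exact-match guide counting, per-sgRNA
negative-binomial statistics, gene-level aggregation with an empirical FDR
from nontargeting controls, per-mouse and bootstrap cohort analyses, a
synthetic screen simulator with known ground truth, and Poisson MOI /
digital-PCR quantification utilities.

## The statistics at the core

**Per-sgRNA test.** Counts are median-of-ratios normalized; guides with
fewer than 100 raw reads across the control (AAV input) samples are
excluded. A weighted least-squares line is fit to log variance vs log mean
over the control samples, and each guide's observed treatment abundance is
tested against a negative binomial with mean mⱼ (control mean) and variance
from the fitted trend, giving underabundance and overabundance tail
p-values. The knockdown phenotype is φⱼ = log₂(treatment mean / control
mean) (pseudocount 0.5).

**Gene aggregation (geopagg).** Per direction, guide p-values are
Benjamini–Hochberg corrected to FDRs xⱼ and combined per gene group by a
weighted geometric mean with Drop-First weights (wⱼ = 0.5 where xⱼ equals
the group minimum, else 1):

    qᵢ = exp( Σⱼ wⱼ ln xⱼ / Σⱼ wⱼ ),   φᵢ = mean(φⱼ),   γᵢ = φᵢ · (−log₁₀ qᵢ)

Pseudo-genes ("amalgams") drawn from the nontargeting controls,
size-matched to the real gene-membership distribution, are scored
identically. Real genes and amalgams are ranked by γᵢ (ascending for
depletion, descending for enrichment) and the empirical FDR at rank i is

    δᵢ = max(cᵢ/i, qᵢ),   cᵢ = #amalgams at ranks 1..i,

made monotone nondecreasing down the ranking. Each gene reports its more
significant direction; a hit is δᵢ < 0.1. Genes targeted at two
transcription start sites (P1/P2) are scored as independent groups.

## Worked example

Simulate a screen with known truth, analyze it, and check recovery:

```bash
craave simulate --out sim/ --seed 12
craave screen --counts sim/counts.tsv --samples sim/samples.tsv \
              --library sim/library.tsv --seed 5 --out results/
```

The default simulation is a 1,000-gene library (5 guides/gene, 250
nontargeting controls) with 2% essential genes at LFC −2 (4 of 5 guides
active), 10 mice at 5×10⁵ neurons each, mean MOI 2, and 5×10⁶ reads per
sample. The `screen` command prints

```
1000 gene groups, 20 hits at FDR < 0.1
```

— the 20 hits in `results/gene_results.tsv` are exactly the 20 simulated
essential genes (`sim/truth_essential_genes.tsv`), all with direction
`depleted`, mean φᵢ ≈ −1.6 (4 active guides at −2 averaged with one inert
guide), and δᵢ ≪ 0.1; no null gene is flagged.

Quantification utilities:

```bash
craave neurons --molecules 5e6 --moi-upper 3 --mice 19
```

reports that 5×10⁶ Cre-inverted episome molecules at an MOI of at most 3
bound ≥ 1.67×10⁶ neurons screened per brain (≥ 3.2×10⁷ for a 19-mouse
cohort), and `craave moi --lambda 3 --colors 3` gives the Poisson
coinfection fractions (26.6% of transduced nuclei carry all three of three
co-injected constructs at total MOI 3).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the stack's headline behaviors from scratch: a full simulated
screen (essential-gene recovery and null flagging rate at FDR < 0.1), a
FASTQ round-trip counting check, a bootstrap cohort-subsampling run, and
the MOI/neuron arithmetic, printing a summary of each.

## Layout

- `craave.library` / `craave.counting` — library TSV loading, exact-match
  FASTQ counting (scan or fixed-offset), count matrices
- `craave.abundance` — normalization, filtering, mean-variance fit, NB tests
- `craave.geopagg` — BH, weighted geometric mean, amalgams, empirical FDR
- `craave.cohort` — per-mouse screens, bootstrap hit recovery
- `craave.simulate` — synthetic libraries, counts, FASTQs with ground truth
- `craave.moi` — coinfection fractions, neuron bounds, dPCR Poisson CIs
- `craave.pipeline` / `craave.cli` — orchestration, provenance, `craave` CLI

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
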