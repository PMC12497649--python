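"""Synthetic pooled-screen generator with known ground truth.

Emulates an AAV episome screen end to end: a CRISPRi library of ~5 guides
per gene plus nontargeting controls, an AAV input pool with lognormal
abundance spread, per-mouse episome sampling (each neuron receives a
Poisson number of guide-carrying virions; only the Cre-positive fraction
contributes recoverable episomes), essential-gene depletion with variable
guide efficacy (neurons carrying an active guide against an essential gene
die, removing all episomes they carry — so co-infection couples
phenotypes), and sequencing-read noise with a log-linear mean-variance
trend. Ground truth (essential genes, per-guide effect sizes, pre-noise
frequencies) is returned for recovery tests.

The guide-level survival model is a stand-in: the probability a neuron
carrying one copy of a guide survives is 2**LFC for LFC <= 0. It
reproduces the stated expected log2 fold change per active guide but only
regime-level behavior (dropout at low coverage, power vs cohort size)
should be read off it quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from craave.counting import CountMatrix, build_count_matrix
from craave.library import NTC_GENE, GuideRecord, LibraryDefinition

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Stated world for the synthetic screen.

    Defaults emulate the desk-scale regime used throughout testing: a
    1,000-gene library at 5 guides/gene with 250 NTCs, 2% essential genes
    at LFC -2 with 4 of 5 guides active, 10 mice at 5e5 neurons each,
    mean MOI 2, and 5e6 reads per sample. ``tss_split_fraction`` of genes
    are split into P1/P2 groups as in real CRISPRi libraries.
    """

    n_genes: int = 1000
    guides_per_gene: int = 5
    n_ntc: int = 250
    tss_split_fraction: float = 0.0
    fraction_essential: float = 0.02
    effect_size_lfc: float = -2.0
    active_guides_per_essential_gene: int = 4
    n_mice: int = 10
    n_controls: int = 2
    neurons_per_mouse: int = 500_000
    moi_mean: float = 2.0
    cre_fraction: float = 1.0
    reads_per_sample: int = 5_000_000
    input_abundance_sigma: float = 0.5
    # log-linear read-noise trend: var = exp(a) * mean**b on top of sampling
    nb_dispersion_a: float = 0.0
    nb_dispersion_b: float = 1.0
    protospacer_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.guides_per_gene < self.active_guides_per_essential_gene:
            raise ValueError("active_guides_per_essential_gene exceeds guides_per_gene")
        for name in ("n_genes", "guides_per_gene", "n_mice", "n_controls",
                     "neurons_per_mouse", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_essential", "cre_fraction", "tss_split_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.moi_mean < 0:
            raise ValueError("moi_mean must be >= 0")


@dataclass
class SimTruth:
    """Ground truth: essential genes, per-guide true LFCs, input frequencies.

    NTC guides and the inactive guides of essential genes always carry
    LFC 0. ``mouse_frequencies`` (filled by :func:`simulate_counts`) holds
    the realized per-mouse episome frequencies before sequencing noise.
    """

    essential_genes: list[str]
    guide_lfc: pd.Series
    input_frequencies: pd.Series | None = None
    mouse_frequencies: pd.DataFrame | None = None


def _random_protospacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for row in rng.integers(0, 4, size=(n - len(out), length)):
            proto = "".join(_BASES[row])
            if proto not in seen:
                seen.add(proto)
                out.append(proto)
    return out


def simulate_library(config: SimulationConfig) -> tuple[LibraryDefinition, SimTruth]:
    """Generate a library and its ground truth under the stated world.

    Essential genes are drawn uniformly; their first
    ``active_guides_per_essential_gene`` guides receive the gene's LFC
    (variable guide efficacy: the rest stay at 0). A
    ``tss_split_fraction`` of genes get their guides split into _P1/_P2
    gene groups scored independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    n_essential = int(round(config.fraction_essential * config.n_genes))
    essential = sorted(rng.choice(genes, size=n_essential, replace=False))
    essential_set = set(essential)
    n_split = int(round(config.tss_split_fraction * config.n_genes))
    split_genes = set(rng.choice(genes, size=n_split, replace=False))

    guides: list[GuideRecord] = []
    lfcs: dict[str, float] = {}
    n_total = config.n_genes * config.guides_per_gene + config.n_ntc
    protos = _random_protospacers(rng, n_total, config.protospacer_length)
    p = 0
    for gene in genes:
        for j in range(config.guides_per_gene):
            gid = f"{gene}_sg{j}"
            tss = ""
            if gene in split_genes:
                tss = "P1" if j < config.guides_per_gene // 2 else "P2"
            guides.append(
                GuideRecord(gid, protos[p], gene, tss_group=tss, is_ntc=False)
            )
            active = (
                gene in essential_set
                and j < config.active_guides_per_essential_gene
            )
            lfcs[gid] = config.effect_size_lfc if active else 0.0
            p += 1
    for j in range(config.n_ntc):
        gid = f"ntc_sg{j}"
        guides.append(GuideRecord(gid, protos[p], NTC_GENE, is_ntc=True))
        lfcs[gid] = 0.0
        p += 1

    library = LibraryDefinition(guides)
    truth = SimTruth(
        essential_genes=essential,
        guide_lfc=pd.Series(lfcs, name="lfc").reindex(library.guide_ids),
    )
    return library, truth


def _sequence_reads(
    rng: np.random.Generator,
    frequencies: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Reads per guide: multinomial sampling plus optional NB overdispersion.

    The log-linear trend var = exp(a) * mean**b adds gamma-distributed
    rate heterogeneity per guide before Poisson read sampling whenever it
    implies var > mean; with the default (a, b) = (0, 1) reads are plain
    multinomial.
    """
    mean = frequencies * config.reads_per_sample
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.exp(config.nb_dispersion_a) * mean**config.nb_dispersion_b
    excess = var - mean
    over = (mean > 0) & (excess > 0)
    if not over.any():
        return rng.multinomial(config.reads_per_sample, frequencies)
    # NB(mean, var) as gamma-Poisson: lambda ~ Gamma(k, mean/k), k = mean^2/excess
    rate = mean.astype(float).copy()
    shape = mean[over] ** 2 / excess[over]
    rate[over] = rng.gamma(shape, mean[over] / shape)
    return rng.poisson(rate)


def simulate_counts(
    library: LibraryDefinition,
    truth: SimTruth,
    config: SimulationConfig,
) -> CountMatrix:
    """Simulate AAV-input (control) and per-mouse (treatment) read counts.

    Input guide frequencies are lognormal(0, sigma) normalized to sum 1.
    Per mouse, each neuron receives Poisson(moi_mean) guide copies drawn
    by input frequency; a Bernoulli(cre_fraction) subset of neurons is
    Cre-positive. Each guide copy independently draws survival with
    probability min(1, 2**LFC); a neuron dies (contributing no episomes)
    if ANY of its copies draws death — co-infection couples phenotypes.
    Surviving Cre-positive neurons contribute all their guide copies as
    episomes; episome frequencies are then sequenced via
    :func:`_sequence_reads`. Controls resample the input frequencies with
    the same read model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_guides = len(library)
    raw = rng.lognormal(mean=0.0, sigma=config.input_abundance_sigma, size=n_guides)
    input_freq = raw / raw.sum()
    truth.input_frequencies = pd.Series(
        input_freq, index=library.guide_ids, name="input_frequency"
    )
    survival = np.minimum(1.0, 2.0 ** truth.guide_lfc.to_numpy())

    samples = []
    mouse_freqs = {}
    for c in range(config.n_controls):
        reads = _sequence_reads(rng, input_freq, config)
        counts = dict(zip(library.guide_ids, (int(x) for x in reads)))
        samples.append((f"aav_input_{c+1}", "control", counts))

    for m in range(config.n_mice):
        copies_per_neuron = rng.poisson(config.moi_mean, size=config.neurons_per_mouse)
        total_copies = int(copies_per_neuron.sum())
        if total_copies == 0:
            raise ValueError(
                "no episomes sampled (moi_mean or neurons_per_mouse too small)"
            )
        guide_of_copy = rng.choice(n_guides, size=total_copies, p=input_freq)
        neuron_of_copy = np.repeat(
            np.arange(config.neurons_per_mouse), copies_per_neuron
        )
        copy_dies = rng.random(total_copies) >= survival[guide_of_copy]
        deaths_per_neuron = np.bincount(
            neuron_of_copy[copy_dies], minlength=config.neurons_per_mouse
        )
        neuron_alive = deaths_per_neuron == 0
        cre_positive = rng.random(config.neurons_per_mouse) < config.cre_fraction
        keep = neuron_alive[neuron_of_copy] & cre_positive[neuron_of_copy]
        episomes = np.bincount(guide_of_copy[keep], minlength=n_guides)
        if episomes.sum() == 0:
            raise ValueError(
                f"mouse {m+1}: zero recoverable episomes "
                "(cre_fraction/moi_mean/neurons_per_mouse too small)"
            )
        freq = episomes / episomes.sum()
        mouse_freqs[f"mouse_{m+1}"] = freq
        reads = _sequence_reads(rng, freq, config)
        counts = dict(zip(library.guide_ids, (int(x) for x in reads)))
        samples.append((f"mouse_{m+1}", "treatment", counts))

    truth.mouse_frequencies = pd.DataFrame(mouse_freqs, index=library.guide_ids)
    meta = {
        f"mouse_{m+1}": {"cohort": "sim", "mouse_id": f"mouse_{m+1}"}
        for m in range(config.n_mice)
    }
    return build_count_matrix(samples, library, sample_meta=meta)


def simulate_fastq(
    counts: dict[str, int],
    library: LibraryDefinition,
    path: str | Path,
    read_length: int = 50,
    offset: int = 10,
    n_random_reads: int = 0,
    seed: int = 0,
) -> int:
    """Write a FASTQ embedding each guide's protospacer in random flanks.

    Emits exactly ``counts[g]`` reads per guide with the protospacer at
    ``offset``, plus ``n_random_reads`` random-sequence reads (expected to
    go unassigned). Round-trip contract:
    ``count_reads(simulate_fastq(c)) == c``. Returns the number of reads
    written. Note random flanks could by chance spell another library
    protospacer; at desk scale (20-nt protospacers) the probability is
    negligible, and the counting stage would report such a read as
    ambiguous rather than miscount it.
    """
    rng = np.random.default_rng(seed)
    max_len = max(len(p) for p in library.protospacers)
    if read_length < offset + max_len:
        raise ValueError("read_length too short for offset + protospacer")
    path = Path(path)
    n_written = 0
    with open(path, "w") as fh:
        for gid, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for guide {gid!r}")
            proto = library[gid].protospacer
            for r in range(n):
                left = "".join(rng.choice(_BASES, size=offset))
                right = "".join(
                    rng.choice(_BASES, size=read_length - offset - len(proto))
                )
                seq = left + proto + right
                fh.write(f"@{gid}:{r}\n{seq}\n+\n{'I' * len(seq)}\n")
                n_written += 1
        for r in range(n_random_reads):
            seq = "".join(rng.choice(_BASES, size=read_length))
            fh.write(f"@random:{r}\n{seq}\n+\n{'I' * len(seq)}\n")
            n_written += 1
    return n_written


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
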