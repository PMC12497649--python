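"""Per-mouse screens and bootstrap cohort-subsampling power analysis.

Each treatment sample (mouse) can be screened alone against the shared AAV
input controls, yielding a genes x mice hit-indicator matrix ("how many
individual mice recover each cohort hit"). The bootstrap analysis draws
mouse subsets of increasing size without replacement, reruns the whole
cohort screen per draw, and reports how much of the full-cohort hit set
each subsample recovers — an empirical estimate of how many mice a screen
design needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from craave.abundance import DEFAULT_FILTER_THRESHOLD, screen_guides
from craave.counting import CountMatrix
from craave.geopagg import DEFAULT_HIT_FDR, aggregate_genes


def _run_screen(
    counts: CountMatrix,
    seed: int,
    filter_threshold: int,
    hit_fdr: float,
    treatment_sample: str | None = None,
    weight_mode: str = "literal",
) -> pd.DataFrame:
    guides = screen_guides(
        counts, filter_threshold=filter_threshold, treatment_sample=treatment_sample
    )
    return aggregate_genes(
        guides,
        gene_groups=counts.library.gene_groups(include_ntc=False),
        ntc_guide_ids=counts.library.ntc_guide_ids,
        seed=seed,
        hit_fdr=hit_fdr,
        weight_mode=weight_mode,
    )


def per_mouse_screens(
    counts: CountMatrix,
    seed: int = 0,
    filter_threshold: int = DEFAULT_FILTER_THRESHOLD,
    hit_fdr: float = DEFAULT_HIT_FDR,
    weight_mode: str = "literal",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Screen each mouse alone against all controls.

    Every per-mouse screen reuses the same controls, coverage filter and
    amalgam seed as the cohort run, so hit differences reflect the mouse,
    not the null. Returns ``(per_mouse_results, hit_matrix)`` where
    ``hit_matrix`` is a genes x mice boolean DataFrame.
    """
    counts.require_roles()
    results: dict[str, pd.DataFrame] = {}
    for mouse in counts.treatment_samples:
        results[mouse] = _run_screen(
            counts, seed, filter_threshold, hit_fdr,
            treatment_sample=mouse, weight_mode=weight_mode,
        )
    genes = sorted(set().union(*(r.index for r in results.values())))
    hit_matrix = pd.DataFrame(
        {m: results[m]["hit"].reindex(genes, fill_value=False) for m in results},
        index=pd.Index(genes, name="group"),
    )
    return results, hit_matrix


@dataclass
class BootstrapSummary:
    """Subsampling results: per-(size, resample) overlap plus hit indicators.

    ``overlap`` has columns size, resample, overlap (fraction of the
    full-cohort hit set recovered). ``hit_indicators`` maps each cohort
    size to a full-cohort-hits x resamples boolean DataFrame.
    """

    sizes: list[int]
    n_resamples: int
    seed: int
    full_hits: list[str]
    overlap: pd.DataFrame
    hit_indicators: dict[int, pd.DataFrame]

    def mean_overlap(self) -> pd.Series:
        return self.overlap.groupby("size")["overlap"].mean()


def bootstrap_hit_recovery(
    counts: CountMatrix,
    sizes: list[int],
    n_resamples: int = 50,
    seed: int = 0,
    filter_threshold: int = DEFAULT_FILTER_THRESHOLD,
    hit_fdr: float = DEFAULT_HIT_FDR,
    weight_mode: str = "literal",
) -> BootstrapSummary:
    """Subsample mice without replacement and measure hit-set recovery.

    For each cohort size s and resample r, draw s treatment mice without
    replacement, rerun the cohort screen on them (same controls, same
    filter threshold; amalgam seeds spawned per resample from the master
    seed), and record |hits(r) intersect hits(full)| / |hits(full)|.
    Draws at s = full cohort are the identity draw, so their overlap is
    1.0 by construction. Called "bootstrap" in the screening literature
    even though draws are without replacement.
    """
    counts.require_roles()
    mice = counts.treatment_samples
    if any(s < 1 or s > len(mice) for s in sizes):
        raise ValueError(f"sizes must lie in [1, {len(mice)}]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    master = np.random.default_rng(seed)
    amalgam_seed = int(master.integers(2**31))
    full = _run_screen(counts, amalgam_seed, filter_threshold, hit_fdr,
                       weight_mode=weight_mode)
    full_hits = list(full.index[full["hit"]])
    if not full_hits:
        raise ValueError("full-cohort hit set is empty; overlap undefined")

    controls = counts.control_samples
    rows = []
    indicators: dict[int, pd.DataFrame] = {}
    for s in sizes:
        ind = pd.DataFrame(
            False,
            index=pd.Index(full_hits, name="group"),
            columns=[f"resample_{r}" for r in range(n_resamples)],
        )
        for r in range(n_resamples):
            sub_seed = int(master.integers(2**31))
            # without-replacement draw; s == full cohort selects every mouse
            chosen = [mice[i] for i in master.permutation(len(mice))[:s]]
            if s == len(mice):
                # identity draw: reuse the full-cohort amalgam seed so the
                # screen is reproduced exactly and overlap is 1 by construction
                sub_seed = amalgam_seed
            sub = counts.subset_samples(controls + chosen)
            res = _run_screen(sub, sub_seed, filter_threshold, hit_fdr,
                              weight_mode=weight_mode)
            sub_hits = set(res.index[res["hit"]])
            recovered = [g for g in full_hits if g in sub_hits]
            ind.loc[recovered, f"resample_{r}"] = True
            rows.append({"size": s, "resample": r,
                         "overlap": len(recovered) / len(full_hits)})
        indicators[s] = ind
    return BootstrapSummary(
        sizes=list(sizes),
        n_resamples=n_resamples,
        seed=seed,
        full_hits=full_hits,
        overlap=pd.DataFrame(rows),
        hit_indicators=indicators,
    )


def per_gene_recovery(
    hit_indicators: pd.DataFrame, hit_set: list[str] | None = None
) -> pd.Series:
    """Fraction of mice (or resamples) re-identifying each full-cohort hit.

    ``hit_indicators`` is a genes x columns boolean DataFrame (columns are
    mice or resamples); ``hit_set`` restricts and orders the reported
    genes (default: all rows). Row means of the indicator matrix equal
    the overlap statistic averaged over columns, which ties the per-gene
    and per-draw summaries together.
    """
    if hit_indicators.empty:
        raise ValueError("empty hit-indicator matrix")
    frac = hit_indicators.mean(axis=1).rename("recovery_fraction")
    if hit_set is not None:
        frac = frac.reindex(hit_set, fill_value=0.0)
    return frac
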