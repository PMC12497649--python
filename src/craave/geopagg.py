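"""Gene-level aggregation: weighted geometric mean of guide FDRs with an
amalgam-gene empirical FDR (geopagg).

Per direction (underabundance / overabundance), guide p-values are
Benjamini-Hochberg corrected to FDRs x_j; within each gene group the FDRs
are combined by a weighted geometric mean

    q_i = exp( sum_j w_j ln x_j / sum_j w_j )

where the Drop-First weights down-weight the group's best guide:
w_j = 0.5 where x_j equals the group minimum, else 1.0. The gene phenotype
phi_i is the arithmetic mean of member phi_j, and the gene score is
gamma_i = phi_i * (-log10 q_i).

Pseudo-genes ("amalgams") assembled from randomly grouped nontargeting
controls, size-matched to the real gene-membership distribution, are scored
identically and provide the empirical null: genes and amalgams are ranked
by gamma (ascending for depletion, descending for enrichment) and the
empirical FDR at rank i is delta_i = max(c_i / i, q_i), where c_i counts
amalgams at ranks 1..i, then constrained to be monotone nondecreasing.
The reported direction per gene is the more significant of the two tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_HIT_FDR = 0.1
_TINY = np.finfo(float).tiny


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (FDRs), clipped to <= 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def drop_first_weights(sorted_fdrs: np.ndarray | list[float]) -> np.ndarray:
    """Drop-First weights: 0.5 for every FDR equal to the group minimum, 1.0 otherwise.

    The literal set condition down-weights all guides tied at the minimum
    (``mode="literal"``, the published rule). A single-guide group's lone
    value is the minimum and gets 0.5.
    """
    x = np.asarray(sorted_fdrs, dtype=float)
    if x.size == 0:
        raise ValueError("empty FDR list")
    return np.where(x == x.min(), 0.5, 1.0)


def single_first_weights(sorted_fdrs: np.ndarray | list[float]) -> np.ndarray:
    """Alternative Drop-First reading: only the first (best) guide gets 0.5."""
    x = np.asarray(sorted_fdrs, dtype=float)
    if x.size == 0:
        raise ValueError("empty FDR list")
    w = np.ones_like(x)
    w[np.argmin(x)] = 0.5
    return w


def weighted_geomean(x_j: np.ndarray | list[float], w_j: np.ndarray | list[float]) -> float:
    """q_i = exp( sum w_j ln x_j / sum w_j ); x_j in (0,1], w_j > 0."""
    x = np.asarray(x_j, dtype=float)
    w = np.asarray(w_j, dtype=float)
    if x.size == 0 or x.size != w.size:
        raise ValueError("x and w must be nonempty and equal length")
    if (x <= 0).any():
        raise ValueError("zero or negative FDR: clip upstream to machine-tiny")
    if (x > 1).any() or (w <= 0).any():
        raise ValueError("require x in (0,1] and w > 0")
    return float(np.exp(np.sum(w * np.log(x)) / np.sum(w)))


def aggregate_phenotype(phi_j: np.ndarray | list[float]) -> float:
    """phi_i: arithmetic mean of member guide phenotypes."""
    phi = np.asarray(phi_j, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phenotype list")
    return float(phi.mean())


def gene_score(phi_i: float, q_i: float) -> float:
    """gamma_i = phi_i * (-log10 q_i)."""
    if not (np.isfinite(phi_i) and 0 < q_i <= 1):
        raise ValueError("require finite phi_i and q_i in (0,1]")
    return float(phi_i * (-np.log10(q_i)))


@dataclass
class AmalgamSet:
    """Pseudo-genes drawn from the NTC pool, size-matched to real genes.

    Membership sizes reproduce the real library's gene-size multiset;
    within one amalgam the member NTC guides are distinct, while the NTC
    pool is reused across amalgams (the pool is far smaller than the gene
    set). Construction is deterministic under the stored seed.
    """

    members: dict[str, list[str]]
    seed: int
    sizes: list[int] = field(init=False)

    def __post_init__(self) -> None:
        for name, guides in self.members.items():
            if len(set(guides)) != len(guides):
                raise ValueError(f"amalgam {name!r} has repeated NTC guides")
        self.sizes = [len(v) for v in self.members.values()]


def build_amalgams(
    ntc_guide_ids: list[str],
    size_distribution: list[int],
    n_amalgams: int,
    seed: int,
) -> AmalgamSet:
    """Draw ``n_amalgams`` pseudo-genes from the NTC pool.

    Each amalgam's size comes from the real-library membership-size
    multiset (used verbatim, permuted, when ``n_amalgams`` equals its
    length; resampled from it otherwise); its members are that many
    distinct NTC guides sampled without replacement within the amalgam.
    """
    if not ntc_guide_ids:
        raise ValueError("empty NTC pool: amalgam genes require nontargeting controls")
    if not size_distribution or n_amalgams < 1:
        raise ValueError("need a nonempty size distribution and n_amalgams >= 1")
    if max(size_distribution) > len(ntc_guide_ids):
        raise ValueError(
            f"largest gene group ({max(size_distribution)}) exceeds NTC pool "
            f"size ({len(ntc_guide_ids)})"
        )
    rng = np.random.default_rng(seed)
    sizes = np.asarray(size_distribution, dtype=int)
    if n_amalgams == sizes.size:
        drawn = rng.permutation(sizes)
    else:
        drawn = rng.choice(sizes, size=n_amalgams, replace=True)
    pool = np.asarray(ntc_guide_ids)
    members = {
        f"amalgam_{i:05d}": list(rng.choice(pool, size=int(m), replace=False))
        for i, m in enumerate(drawn)
    }
    return AmalgamSet(members=members, seed=seed)


def empirical_fdr(ranked: pd.DataFrame) -> pd.Series:
    """Empirical FDR delta_i from a ranked gene + amalgam table.

    ``ranked`` must already be sorted in ranking order and carry columns
    ``q`` and ``is_amalgam``. At rank i (1-based), c_i counts amalgam
    entries at ranks 1..i and delta_i = max(c_i / i, q_i); a monotone pass
    then enforces delta_i >= delta_{i-1}. Returns delta for every entry
    (amalgams included; callers drop them from reported tables).
    """
    if ranked.empty:
        raise ValueError("empty ranking")
    i = np.arange(1, len(ranked) + 1)
    c = np.cumsum(ranked["is_amalgam"].to_numpy(dtype=float))
    delta = np.maximum(c / i, ranked["q"].to_numpy(dtype=float))
    delta = np.maximum.accumulate(delta)
    return pd.Series(delta, index=ranked.index, name="delta")


def _score_groups(
    guide_results: pd.DataFrame,
    groups: dict[str, list[str]],
    direction: str,
    weight_mode: str,
    hit_fdr: float,
) -> pd.DataFrame:
    """q, phi, gamma per group for one direction; guide_results indexed by guide_id
    with columns x_under/x_over (BH FDRs) and phi."""
    col = f"x_{direction}"
    weight_fn = drop_first_weights if weight_mode == "literal" else single_first_weights
    rows = {}
    for key, guide_ids in groups.items():
        sub = guide_results.loc[guide_results.index.intersection(guide_ids)]
        if sub.empty:  # every member failed the coverage filter
            continue
        x = np.sort(np.clip(sub[col].to_numpy(dtype=float), _TINY, 1.0))
        w = weight_fn(x)
        q = weighted_geomean(x, w)
        phi = aggregate_phenotype(sub["phi"].to_numpy())
        rows[key] = {
            "q": q,
            "phi": phi,
            "gamma": gene_score(phi, q),
            "n_guides": len(sub),
            "n_significant_guides": int((sub[col] < hit_fdr).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _rank_and_fdr(scored: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Sort by gamma (ascending for under/depletion, descending for over),
    attach delta, drop amalgams."""
    ascending = direction == "under"
    out = scored.sort_values(
        ["gamma", "q"], ascending=[ascending, True], kind="mergesort"
    )
    out["delta"] = empirical_fdr(out)
    return out.loc[~out["is_amalgam"]].drop(columns="is_amalgam")


def combine_directions(
    under: pd.DataFrame, over: pd.DataFrame, hit_fdr: float = DEFAULT_HIT_FDR
) -> pd.DataFrame:
    """Report each gene's more significant direction.

    Winner has the smaller delta; ties break to the smaller q, then to
    depleted. Adds ``direction`` in {depleted, enriched} and the boolean
    ``hit`` flag (delta < hit_fdr).
    """
    common = under.index
    if not common.equals(over.index):
        over = over.reindex(common)
    u_delta = under["delta"].to_numpy()
    o_delta = over["delta"].to_numpy()
    u_q = under["q"].to_numpy()
    o_q = over["q"].to_numpy()
    pick_under = (u_delta < o_delta) | ((u_delta == o_delta) & (u_q <= o_q))
    out = pd.DataFrame(index=common)
    for col in ("q", "phi", "gamma", "delta", "n_guides", "n_significant_guides"):
        out[col] = np.where(pick_under, under[col].to_numpy(), over[col].to_numpy())
    out["direction"] = np.where(pick_under, "depleted", "enriched")
    out["delta_under"] = u_delta
    out["delta_over"] = o_delta
    out["hit"] = out["delta"] < hit_fdr
    out["one_guide_driven"] = out["hit"] & (out["n_significant_guides"] == 1)
    out["n_guides"] = out["n_guides"].astype(int)
    out["n_significant_guides"] = out["n_significant_guides"].astype(int)
    return out


def aggregate_genes(
    guide_results: pd.DataFrame,
    gene_groups: dict[str, list[str]],
    ntc_guide_ids: list[str],
    seed: int,
    n_amalgams: int | None = None,
    hit_fdr: float = DEFAULT_HIT_FDR,
    weight_mode: str = "literal",
) -> pd.DataFrame:
    """Full geopagg pass: BH, group scores, amalgam null, delta, direction.

    ``guide_results`` is the per-sgRNA table from
    :func:`craave.abundance.screen_guides` (indexed by guide_id, with
    ``p_under``, ``p_over``, ``phi``). ``gene_groups`` maps real group
    keys to member guide_ids (no NTCs). Returns one row per real gene
    group, indexed by group key, sorted by delta then gamma.
    """
    if weight_mode not in ("literal", "single_first"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    guide_results = guide_results.copy()
    # BH across the full retained guide family, NTCs included
    guide_results["x_under"] = bh_adjust(guide_results["p_under"].to_numpy())
    guide_results["x_over"] = bh_adjust(guide_results["p_over"].to_numpy())

    retained_ntc = [g for g in ntc_guide_ids if g in guide_results.index]
    sizes = [
        len(guide_results.index.intersection(members))
        for members in gene_groups.values()
    ]
    sizes = [s for s in sizes if s > 0]
    if not sizes:
        raise ValueError("no gene group has any retained guide")
    amalgams = build_amalgams(
        retained_ntc,
        size_distribution=sizes,
        n_amalgams=n_amalgams or len(sizes),
        seed=seed,
    )

    per_direction = {}
    for direction in ("under", "over"):
        real = _score_groups(guide_results, gene_groups, direction, weight_mode, hit_fdr)
        real["is_amalgam"] = False
        null = _score_groups(
            guide_results, amalgams.members, direction, weight_mode, hit_fdr
        )
        null["is_amalgam"] = True
        scored = pd.concat([real, null])
        per_direction[direction] = _rank_and_fdr(scored, direction)

    result = combine_directions(
        per_direction["under"].sort_index(),
        per_direction["over"].sort_index(),
        hit_fdr=hit_fdr,
    )
    result.index.name = "group"
    result.attrs["amalgam_seed"] = seed
    result.attrs["n_amalgams"] = len(amalgams.members)
    return result.sort_values(["delta", "gamma"], kind="mergesort")
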