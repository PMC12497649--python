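"""End-to-end orchestration: count matrix -> guide stats -> gene table.

The pipeline bundles the screening stages in their canonical order
(median normalization, coverage filter, mean-variance fit, NB guide
tests, BH correction, geopagg aggregation with amalgam empirical FDR) and
writes guide/gene TSVs plus a JSON provenance record (config, seeds,
version, config hash) so any output can be traced to the run that made
it. Reruns with identical config and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import craave
from craave.abundance import (
    DEFAULT_FILTER_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    screen_guides,
)
from craave.counting import CountMatrix
from craave.geopagg import DEFAULT_HIT_FDR, aggregate_genes

logger = logging.getLogger("craave")


@dataclass
class RunConfig:
    """Knobs for one screen run, serialized into the provenance record."""

    filter_threshold: int = DEFAULT_FILTER_THRESHOLD
    hit_fdr: float = DEFAULT_HIT_FDR
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int = 0
    per_mouse: bool = False
    weight_mode: str = "literal"  # drop-first weighting: literal | single_first
    n_amalgams: int | None = None
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScreenResult:
    guide_results: pd.DataFrame
    gene_results: pd.DataFrame
    per_mouse_hits: pd.DataFrame | None
    config: RunConfig


def run_screen_pipeline(
    counts: CountMatrix,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> ScreenResult:
    """Run the cohort screen (optionally plus per-mouse screens) and write outputs."""
    config = config or RunConfig()
    counts.require_roles()
    logger.info(
        "screen: %d guides, %d control + %d treatment samples",
        len(counts.library), len(counts.control_samples),
        len(counts.treatment_samples),
    )
    guide_results = screen_guides(
        counts,
        filter_threshold=config.filter_threshold,
        pseudocount=config.pseudocount,
    )
    n_excluded = len(counts.library) - len(guide_results)
    logger.info(
        "coverage filter (<%d control reads): %d guides excluded, %d retained",
        config.filter_threshold, n_excluded, len(guide_results),
    )
    gene_results = aggregate_genes(
        guide_results,
        gene_groups=counts.library.gene_groups(include_ntc=False),
        ntc_guide_ids=counts.library.ntc_guide_ids,
        seed=config.seed,
        n_amalgams=config.n_amalgams,
        hit_fdr=config.hit_fdr,
        weight_mode=config.weight_mode,
    )
    logger.info(
        "geopagg: %d gene groups, %d hits at empirical FDR < %g",
        len(gene_results), int(gene_results["hit"].sum()), config.hit_fdr,
    )

    per_mouse_hits = None
    if config.per_mouse:
        from craave.cohort import per_mouse_screens

        _, per_mouse_hits = per_mouse_screens(
            counts,
            seed=config.seed,
            filter_threshold=config.filter_threshold,
            hit_fdr=config.hit_fdr,
            weight_mode=config.weight_mode,
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        guide_results.rename_axis("guide_id").to_csv(
            out_dir / "guide_results.tsv", sep="\t"
        )
        gene_results.rename_axis("group").to_csv(
            out_dir / "gene_results.tsv", sep="\t"
        )
        if per_mouse_hits is not None:
            per_mouse_hits.to_csv(out_dir / "per_mouse_hits.tsv", sep="\t")
        provenance = {
            "tool": "craave",
            "version": craave.__version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "n_guides_retained": len(guide_results),
            "n_gene_groups": len(gene_results),
            "n_hits": int(gene_results["hit"].sum()),
            "amalgam_seed": gene_results.attrs.get("amalgam_seed"),
            "n_amalgams": gene_results.attrs.get("n_amalgams"),
        }
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str) + "\n"
        )
    return ScreenResult(
        guide_results=guide_results,
        gene_results=gene_results,
        per_mouse_hits=per_mouse_hits,
        config=config,
    )
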