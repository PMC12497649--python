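"""sgRNA library reference: guide records, gene groups, TSV loading.

A library is an ordered set of guides, each carrying a protospacer (the
~19-20 nt variable targeting sequence), a gene label, an optional
transcription-start-site group (P1/P2 — genes targeted at two TSSs are
scored as two independent gene groups), and a nontargeting-control flag.
Nontargeting controls (NTCs) carry the reserved gene label ``NTC`` and
supply the empirical null for gene aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NTC_GENE = "NTC"
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA library entry."""

    guide_id: str
    protospacer: str
    gene: str
    tss_group: str = ""
    is_ntc: bool = False

    @property
    def group_key(self) -> str:
        """Gene-group key: gene plus TSS suffix, e.g. ``GeneA_P1``.

        P1 and P2 guide sets of the same gene form distinct groups and are
        aggregated independently. NTC guides all map to the ``NTC`` group.
        """
        if self.is_ntc:
            return NTC_GENE
        if self.tss_group:
            return f"{self.gene}_{self.tss_group}"
        return self.gene


@dataclass
class LibraryDefinition:
    """Validated, ordered collection of guides with gene-group indexing."""

    guides: list[GuideRecord]
    _by_id: dict[str, GuideRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.guides:
            raise ValueError("library contains no guides")
        seen_ids: dict[str, str] = {}
        seen_protos: dict[str, str] = {}
        for g in self.guides:
            if g.guide_id in seen_ids:
                raise ValueError(f"duplicate guide_id {g.guide_id!r}")
            seen_ids[g.guide_id] = g.guide_id
            if not g.protospacer or set(g.protospacer) - _VALID_BASES:
                raise ValueError(
                    f"guide {g.guide_id!r}: protospacer {g.protospacer!r} "
                    "contains non-ACGT characters or is empty"
                )
            if g.protospacer in seen_protos:
                raise ValueError(
                    f"duplicate protospacer shared by guides "
                    f"{seen_protos[g.protospacer]!r} and {g.guide_id!r}"
                )
            seen_protos[g.protospacer] = g.guide_id
            if not g.is_ntc and not g.gene:
                raise ValueError(f"guide {g.guide_id!r}: targeting guide lacks a gene")
            if g.is_ntc and g.gene != NTC_GENE:
                raise ValueError(
                    f"guide {g.guide_id!r}: NTC guides must carry gene label {NTC_GENE!r}"
                )
        self._by_id = {g.guide_id: g for g in self.guides}

    def __len__(self) -> int:
        return len(self.guides)

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def protospacers(self) -> dict[str, str]:
        """Mapping protospacer -> guide_id (unique by construction)."""
        return {g.protospacer: g.guide_id for g in self.guides}

    @property
    def ntc_guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides if g.is_ntc]

    def gene_groups(self, include_ntc: bool = True) -> dict[str, list[str]]:
        """Group key -> member guide_ids, in library order."""
        groups: dict[str, list[str]] = {}
        for g in self.guides:
            if g.is_ntc and not include_ntc:
                continue
            groups.setdefault(g.group_key, []).append(g.guide_id)
        return groups

    def group_sizes(self) -> dict[str, int]:
        """Membership size M_i per real (non-NTC) gene group."""
        return {k: len(v) for k, v in self.gene_groups(include_ntc=False).items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.guides],
                "protospacer": [g.protospacer for g in self.guides],
                "gene": [g.gene for g in self.guides],
                "tss_group": [g.tss_group for g in self.guides],
                "is_ntc": [g.is_ntc for g in self.guides],
                "group": [g.group_key for g in self.guides],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().drop(columns="group").to_csv(path, sep="\t", index=False)


_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


def _parse_bool(value: object, guide_id: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"guide {guide_id!r}: cannot parse is_ntc value {value!r}")


def load_library(
    path: str | Path, expected_length: int | None = None
) -> LibraryDefinition:
    """Load and validate an sgRNA library reference TSV.

    The file must have a header with ``guide_id``, ``protospacer``, ``gene``
    and ``is_ntc`` columns; ``tss_group`` is optional. Protospacers are
    uppercased. Duplicate guide_ids or protospacers, non-ACGT protospacer
    characters, and (if ``expected_length`` is given) off-length
    protospacers are load errors naming the offending guide.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"library file {path} has no guide rows")
    required = {"guide_id", "protospacer", "gene", "is_ntc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file {path} missing columns: {sorted(missing)}")
    has_tss = "tss_group" in df.columns
    guides = []
    for row in df.itertuples(index=False):
        proto = str(row.protospacer).strip().upper()
        if expected_length is not None and len(proto) != expected_length:
            raise ValueError(
                f"guide {row.guide_id!r}: protospacer length {len(proto)} "
                f"!= expected {expected_length}"
            )
        guides.append(
            GuideRecord(
                guide_id=str(row.guide_id).strip(),
                protospacer=proto,
                gene=str(row.gene).strip(),
                tss_group=str(row.tss_group).strip() if has_tss else "",
                is_ntc=_parse_bool(row.is_ntc, str(row.guide_id)),
            )
        )
    return LibraryDefinition(guides)
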