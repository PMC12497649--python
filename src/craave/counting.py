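"""Exact-match protospacer counting and the guide x sample count matrix.

Reads are assigned to guides by exact string matching only — no mismatch
rescue, no alignment. The default ``scan`` policy slides a window over each
read and looks the window up in a hash of all library protospacers, so the
amplicon layout (where the protospacer sits in the read) need not be known.
A ``fixed`` policy checks a single stated offset and is faster. Any read
matching two or more distinct protospacers (possible under scan with nested
sequences) is counted as ambiguous, never assigned.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from craave.library import LibraryDefinition

ROLES = ("control", "treatment")


@dataclass(frozen=True)
class CountingStats:
    """Per-FASTQ read accounting; assigned + unassigned + ambiguous = reads_seen."""

    reads_seen: int
    assigned: int
    unassigned: int
    ambiguous: int

    def __post_init__(self) -> None:
        if self.assigned + self.unassigned + self.ambiguous != self.reads_seen:
            raise AssertionError("read accounting does not conserve total reads")


@dataclass
class OffsetPolicy:
    """Where to look for the protospacer in each read.

    mode ``scan`` searches every window; ``fixed`` checks only windows
    starting at ``start``. ``revcomp`` additionally searches the reverse
    complement of the read (off by default: amplicon sequencing has fixed
    orientation).
    """

    mode: str = "scan"
    start: int = 0
    revcomp: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("scan", "fixed"):
            raise ValueError(f"unknown offset policy mode {self.mode!r}")
        if self.start < 0:
            raise ValueError("fixed offset must be >= 0")


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle: IO[str]) -> Iterator[str]:
    """Yield read sequences; raise on malformed records with the record index."""
    record = 0
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record at record index {record}")
        seq = seq.strip()
        if len(qual.strip()) != len(seq):
            raise ValueError(
                f"malformed FASTQ record at record index {record}: "
                "quality length != sequence length"
            )
        yield seq
        record += 1


def _match_read(
    seq: str,
    lookup: dict[str, str],
    lengths: tuple[int, ...],
    policy: OffsetPolicy,
) -> set[str]:
    """Distinct guide_ids whose protospacer occurs exactly in the read."""
    hits: set[str] = set()
    seqs = [seq] if not policy.revcomp else [seq, reverse_complement(seq)]
    for s in seqs:
        n = len(s)
        for L in lengths:
            if policy.mode == "fixed":
                window = s[policy.start : policy.start + L]
                if len(window) == L and window in lookup:
                    hits.add(lookup[window])
            else:
                for i in range(n - L + 1):
                    window = s[i : i + L]
                    if window in lookup:
                        hits.add(lookup[window])
    return hits


def count_reads(
    fastq: str | Path | Iterable[str],
    library: LibraryDefinition,
    offset_policy: OffsetPolicy | None = None,
) -> tuple[dict[str, int], CountingStats]:
    """Count reads per guide by exact protospacer matching.

    ``fastq`` may be a path (plain or ``.gz``) or an iterable of read
    sequences. Each read is assigned to at most one guide; reads matching
    no protospacer are unassigned, reads matching >= 2 distinct
    protospacers are ambiguous. Returns ``(counts, stats)`` with counts
    keyed by every library guide (zeros included).
    """
    if len(library) == 0:
        raise ValueError("empty library")
    policy = offset_policy or OffsetPolicy()
    lookup = library.protospacers
    lengths = tuple(sorted({len(p) for p in lookup}))
    counts = {gid: 0 for gid in library.guide_ids}
    seen = assigned = ambiguous = 0

    if isinstance(fastq, (str, Path)):
        handle = _open_maybe_gzip(fastq)
        reads: Iterable[str] = _iter_fastq(handle)
    else:
        handle = None
        reads = fastq
    try:
        for seq in reads:
            seen += 1
            hits = _match_read(seq.upper(), lookup, lengths, policy)
            if len(hits) == 1:
                counts[hits.pop()] += 1
                assigned += 1
            elif len(hits) > 1:
                ambiguous += 1
    finally:
        if handle is not None:
            handle.close()

    stats = CountingStats(
        reads_seen=seen,
        assigned=assigned,
        unassigned=seen - assigned - ambiguous,
        ambiguous=ambiguous,
    )
    return counts, stats


@dataclass
class CountMatrix:
    """Guide x sample integer counts with per-sample role metadata.

    ``counts`` rows follow library order and cover the full guide set
    (guides never observed are zero rows). ``samples`` carries one row per
    sample with ``role`` in {control, treatment} plus optional ``cohort``
    and ``mouse_id``. Screening operations require at least one control
    (AAV input) and one treatment (mouse) column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library: LibraryDefinition = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.index) != self.library.guide_ids:
            raise ValueError("count matrix rows must equal the library guide set, in order")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count matrix columns must match the sample sheet")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "control"])

    @property
    def treatment_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "treatment"])

    def require_roles(self) -> None:
        """Screening contract: >= 1 control and >= 1 treatment column."""
        if not self.control_samples:
            raise ValueError("no control (AAV input) samples present")
        if not self.treatment_samples:
            raise ValueError("no treatment (mouse) samples present")

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[sample_ids],
            samples=self.samples.loc[sample_ids],
            library=self.library,
        )

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("guide_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        library: LibraryDefinition,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id", dtype=str)
        return cls(counts=counts, samples=samples, library=library)


def build_count_matrix(
    sample_counts: Iterable[tuple[str, str, dict[str, int]]],
    library: LibraryDefinition,
    sample_meta: dict[str, dict[str, str]] | None = None,
) -> CountMatrix:
    """Assemble per-sample count dicts into a CountMatrix.

    ``sample_counts`` yields ``(sample_id, role, counts)`` triples; counts
    are keyed by guide_id, missing guides are zero-filled. Duplicate
    sample_ids and unknown roles are errors.
    """
    sample_ids: list[str] = []
    roles: list[str] = []
    columns: dict[str, pd.Series] = {}
    known = set(library.guide_ids)
    for sample_id, role, counts in sample_counts:
        if sample_id in columns:
            raise ValueError(f"duplicate sample_id {sample_id!r}")
        if role not in ROLES:
            raise ValueError(f"sample {sample_id!r}: role {role!r} not in {ROLES}")
        unknown = set(counts) - known
        if unknown:
            raise ValueError(
                f"sample {sample_id!r}: counts for guides not in library: "
                f"{sorted(unknown)[:5]}"
            )
        sample_ids.append(sample_id)
        roles.append(role)
        columns[sample_id] = pd.Series(counts, dtype=np.int64)
    if not sample_ids:
        raise ValueError("no samples provided")
    counts_df = (
        pd.DataFrame(columns)
        .reindex(index=library.guide_ids, columns=sample_ids)
        .fillna(0)
        .astype(np.int64)
    )
    samples_df = pd.DataFrame({"role": roles}, index=pd.Index(sample_ids, name="sample_id"))
    samples_df["cohort"] = [
        (sample_meta or {}).get(s, {}).get("cohort", "") for s in sample_ids
    ]
    samples_df["mouse_id"] = [
        (sample_meta or {}).get(s, {}).get("mouse_id", s) for s in sample_ids
    ]
    return CountMatrix(counts=counts_df, samples=samples_df, library=library)
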