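"""Read cleaning and unique-sequence collapsing.

Raw reads are adapter-trimmed, gated on length (18-26 nt by default),
mean quality, ambiguous bases and mononucleotide entropy, then collapsed
to unique sequences with per-sample counts. Every rejected read is
tallied by reason so input = accepted + rejected holds per sample.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seqio import FastqRecord, read_fastq, write_table

MIN_ADAPTER_SEED = 6

REJECT_REASONS = (
    "adapter_dimer", "no_adapter", "length", "quality", "ambiguous",
    "low_complexity",
)


@dataclass(frozen=True)
class CleanParams:
    adapter: str
    min_len: int = 18
    max_len: int = 26
    max_ambiguous: int = 0
    entropy_min: float = 1.0    # bits/symbol over mononucleotide frequencies
    qual_min: float = 20.0      # mean Phred floor
    max_adapter_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len exceeds max_len")
        if self.entropy_min < 0:
            raise ValueError("entropy_min must be non-negative")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass(frozen=True)
class Rejection:
    reason: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(read: str, adapter: str,
                 max_adapter_mismatch: int = 0) -> str | Rejection:
    """Return the insert upstream of the leftmost adapter occurrence.

    An occurrence is an adapter prefix of at least MIN_ADAPTER_SEED nt
    matching with at most ``max_adapter_mismatch`` substitutions. A read
    that begins with the adapter is an adapter dimer.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(read)
    for p in range(n):
        span = min(len(adapter), n - p)
        if span < MIN_ADAPTER_SEED:
            break
        if _hamming(read[p:p + span], adapter[:span]) <= max_adapter_mismatch:
            if p == 0:
                return Rejection("adapter_dimer")
            return read[:p]
    return Rejection("no_adapter")


def sequence_entropy(seq: str) -> float:
    """Shannon entropy (bits/symbol) of the mononucleotide composition."""
    if not seq:
        return 0.0
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def filter_read(insert: str, qualities: Iterable[int],
                params: CleanParams) -> str | Rejection:
    """Gate an adapter-trimmed insert; returns it or a reason."""
    if not params.min_len <= len(insert) <= params.max_len:
        return Rejection("length")
    quals = list(qualities)
    if quals and sum(quals) / len(quals) < params.qual_min:
        return Rejection("quality")
    if sum(1 for b in insert if b not in "ACGU") > params.max_ambiguous:
        return Rejection("ambiguous")
    if sequence_entropy(insert) < params.entropy_min:
        return Rejection("low_complexity")
    return insert


@dataclass
class SampleStats:
    input: int = 0
    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return self.input == self.accepted + sum(self.rejected.values())


@dataclass
class UniqueSequenceTable:
    """Unique sequences x samples, with per-sample cleaning statistics."""

    counts: pd.DataFrame                 # index: sequence, columns: samples
    stats: dict[str, SampleStats]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, path: str | Path) -> None:
        write_table(self.counts, path, index_label="sequence")

    def write_log(self, path: str | Path) -> None:
        rows = []
        for sample, st in self.stats.items():
            row = {"sample": sample, "input": st.input,
                   "accepted": st.accepted}
            for reason in REJECT_REASONS:
                row[f"rejected_{reason}"] = st.rejected.get(reason, 0)
            rows.append(row)
        write_table(pd.DataFrame(rows), path, index=False)


def collapse_unique(accepted: Mapping[str, Iterable[str]],
                    stats: Mapping[str, SampleStats] | None = None,
                    ) -> UniqueSequenceTable:
    """Collapse accepted inserts to a unique-sequence count table.

    Rows are ordered by total count descending, ties lexicographically, so
    the table is invariant under permutation of the input reads.
    """
    samples = list(accepted)
    counters = {s: Counter(accepted[s]) for s in samples}
    all_seqs = sorted(set().union(*counters.values()) if counters else set())
    df = pd.DataFrame(
        {s: [counters[s].get(q, 0) for q in all_seqs] for s in samples},
        index=pd.Index(all_seqs, name="sequence"),
        dtype=int,
    )
    if len(df):
        order = (-df.sum(axis=1)).argsort(kind="stable")
        df = df.iloc[order]
    if stats is None:
        stats = {
            s: SampleStats(input=sum(counters[s].values()),
                           accepted=sum(counters[s].values()))
            for s in samples
        }
    return UniqueSequenceTable(df, dict(stats))


def clean_reads(reads: Iterable[FastqRecord],
                params: CleanParams) -> tuple[list[str], SampleStats]:
    """Trim and filter one sample's reads; returns accepted inserts."""
    stats = SampleStats()
    accepted: list[str] = []
    for rec in reads:
        stats.input += 1
        trimmed = trim_adapter(rec.sequence, params.adapter,
                               params.max_adapter_mismatch)
        if isinstance(trimmed, Rejection):
            stats.rejected[trimmed.reason] += 1
            continue
        result = filter_read(trimmed, rec.qualities[:len(trimmed)], params)
        if isinstance(result, Rejection):
            stats.rejected[result.reason] += 1
            continue
        stats.accepted += 1
        accepted.append(result)
    return accepted, stats


def preprocess_samples(fastq_paths: Mapping[str, str | Path],
                       params: CleanParams) -> UniqueSequenceTable:
    """Clean each sample's FASTQ and collapse into one table."""
    accepted: dict[str, list[str]] = {}
    stats: dict[str, SampleStats] = {}
    for sample, path in fastq_paths.items():
        accepted[sample], stats[sample] = clean_reads(read_fastq(path), params)
    return collapse_unique(accepted, stats)
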