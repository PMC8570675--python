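"""Contaminant removal and precursor mapping of unique sequences.

Unique sequences are first removed if they occur verbatim inside any
contaminant ncRNA record, then placed on precursor hairpins by ungapped
alignment allowing at most one internal mismatch and a bounded amount of
5'/3' end variation relative to an annotated mature arm. Placements on
the arm opposite a precursor's sole annotated mature become novel
candidates, handed to the hairpin module as an 80 nt flank window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import hairpin as hp
from .preprocess import UniqueSequenceTable
from .seqio import FastaRecord, read_fasta, write_table

DEFAULT_MAX_MISMATCH = 1
DEFAULT_MAX_END_SHIFT = 2
FLANK_WINDOW = 80

CLASSES = ("known_mature", "novel_arm_candidate", "contaminant", "unmapped")


@dataclass(frozen=True)
class MatureAnnotation:
    name: str
    start: int       # 0-based half-open on the precursor
    end: int
    arm: str         # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if self.start >= self.end:
            raise ValueError("empty mature interval")


@dataclass(frozen=True)
class PrecursorRecord:
    id: str
    sequence: str
    matures: tuple[MatureAnnotation, ...]

    def __post_init__(self) -> None:
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: mature {m.name} exceeds precursor bounds")


class PrecursorReference:
    """Ordered collection of precursor hairpins with mature annotations."""

    def __init__(self, records: Sequence[PrecursorRecord]):
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate precursor ids")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, pid: str) -> PrecursorRecord:
        return self._by_id[pid]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PrecursorReference":
        """Read precursors; mature arms are encoded in the description as
        ``mature5p=<start>-<end>`` / ``mature3p=<start>-<end>`` tokens."""
        records = []
        for rec in read_fasta(path):
            matures = []
            for token in rec.description.split():
                if token.startswith("mature5p=") or token.startswith("mature3p="):
                    arm = token[6:8]
                    start, end = token.split("=")[1].split("-")
                    matures.append(MatureAnnotation(
                        f"{rec.id}-{arm}", int(start), int(end), arm))
            records.append(PrecursorRecord(rec.id, rec.sequence,
                                           tuple(matures)))
        return cls(records)

    def to_fasta_records(self) -> list[FastaRecord]:
        out = []
        for r in self.records:
            desc = " ".join(f"mature{m.arm}={m.start}-{m.end}"
                            for m in r.matures)
            out.append(FastaRecord(r.id, r.sequence, desc))
        return out


@dataclass(frozen=True)
class Hit:
    precursor: str
    offset: int
    mismatches: int
    mature: str | None       # name of the matched mature arm, if consistent
    end_shift: int           # |5' shift| + |3' shift| vs that mature


@dataclass(frozen=True)
class AnnotationRow:
    sequence: str
    klass: str
    precursor: str | None = None
    offset: int | None = None
    mismatches: int | None = None
    end_shift: int | None = None
    assigned_id: str | None = None     # mature or novel-candidate id
    flank_start: int | None = None
    flank_end: int | None = None


def remove_contaminants(table: UniqueSequenceTable,
                        contaminants: Iterable[FastaRecord],
                        ) -> tuple[UniqueSequenceTable, UniqueSequenceTable]:
    """Partition the table into (retained, contaminant).

    A sequence is a contaminant iff it is an exact substring of any
    contaminant record (sense strand only). Counts are conserved across
    the partition.
    """
    contam_seqs = [c.sequence for c in contaminants]
    mask = [any(seq in c for c in contam_seqs) for seq in table.counts.index]
    retained = UniqueSequenceTable(table.counts.loc[[not m for m in mask]],
                                  table.stats)
    removed = UniqueSequenceTable(table.counts.loc[mask], table.stats)
    return retained, removed


def map_to_precursors(sequence: str, reference: PrecursorReference,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      max_end_shift: int = DEFAULT_MAX_END_SHIFT,
                      ) -> list[Hit]:
    """All ungapped placements with at most ``max_mismatch`` substitutions.

    Hits are ranked by (mismatches, end shift vs the closest consistent
    mature arm, reference order, offset); a hit with no mature-consistent
    arm sorts after equal-mismatch consistent ones.
    """
    L = len(sequence)
    hits: list[tuple[tuple, Hit]] = []
    for ridx, rec in enumerate(reference):
        pre = rec.sequence
        for off in range(len(pre) - L + 1):
            mm = sum(a != b for a, b in zip(sequence, pre[off:off + L]))
            if mm > max_mismatch:
                continue
            mature_name = None
            best_shift = None
            for m in rec.matures:
                s5 = abs(off - m.start)
                s3 = abs((off + L) - m.end)
                if s5 <= max_end_shift and s3 <= max_end_shift:
                    if best_shift is None or s5 + s3 < best_shift:
                        best_shift = s5 + s3
                        mature_name = m.name
            shift = best_shift if best_shift is not None else 0
            key = (mm, best_shift if best_shift is not None else max_end_shift * 2 + 1,
                   ridx, off)
            hits.append((key, Hit(rec.id, off, mm, mature_name, shift)))
    hits.sort(key=lambda t: t[0])
    return [h for _, h in hits]


@lru_cache(maxsize=4096)
def _loop_interval(sequence: str) -> tuple[int, int] | None:
    """Terminal-loop interval of the dominant hairpin (fold-based)."""
    try:
        st = hp.fold(sequence)
    except ValueError:
        return None
    partner = st.partner
    if not partner:
        return None
    best = None
    for i, j in st.pairs:
        if not any(x in partner for x in range(i + 1, j)):
            chain = hp._stem_chain(partner, (i, j))
            if best is None or len(chain) > best[0]:
                best = (len(chain), i, j)
    if best is None:
        return None
    _, i, j = best
    return i + 1, j  # unpaired loop, half-open


def _placement_arm(rec: PrecursorRecord, offset: int, length: int) -> str | None:
    """Arm of an ungapped placement, from the folded terminal loop.

    Falls back to the precursor midpoint when the fold yields no hairpin.
    Placements straddling the loop have no arm.
    """
    loop = _loop_interval(rec.sequence)
    if loop is None:
        mid = len(rec.sequence) // 2
        loop = (mid, mid)
    ls, le = loop
    center = offset + length / 2
    if offset + length <= le and center < (ls + le) / 2:
        return "5p"
    if offset >= ls and center >= (ls + le) / 2:
        return "3p"
    if offset + length <= ls:
        return "5p"
    if offset >= le:
        return "3p"
    return None


def classify(sequence: str, hits: Sequence[Hit],
             reference: PrecursorReference,
             flank: int = FLANK_WINDOW) -> AnnotationRow:
    """Assign one class to a (contaminant-free) unique sequence.

    The best hit decides: mature-consistent -> known_mature; on the arm
    opposite a sole annotated mature -> novel_arm_candidate, with a flank
    window of ``flank`` nt centred on the placement and clipped to the
    precursor; otherwise unmapped.
    """
    if not hits:
        return AnnotationRow(sequence, "unmapped")
    best = hits[0]
    if best.mature is not None:
        return AnnotationRow(sequence, "known_mature", best.precursor,
                             best.offset, best.mismatches, best.end_shift,
                             assigned_id=best.mature)
    # novel candidate: pick the first-ranked hit landing opposite a sole
    # annotated mature, if any
    for hit in hits:
        rec = reference[hit.precursor]
        if len(rec.matures) != 1:
            continue
        arm = _placement_arm(rec, hit.offset, len(sequence))
        if arm is None or arm == rec.matures[0].arm:
            continue
        center = hit.offset + len(sequence) // 2
        half = flank // 2
        fs = max(0, center - half)
        fe = min(len(rec.sequence), center + half)
        return AnnotationRow(
            sequence, "novel_arm_candidate", hit.precursor, hit.offset,
            hit.mismatches, 0,
            assigned_id=f"{hit.precursor}-{arm}-novel",
            flank_start=fs, flank_end=fe)
    return AnnotationRow(sequence, "unmapped", best.precursor, best.offset,
                         best.mismatches)


@dataclass
class AnnotationResult:
    """Per-sequence classes joined to the per-sample count columns."""

    rows: pd.DataFrame          # indexed by sequence
    counts: pd.DataFrame        # same index, per-sample counts

    def write(self, path: str | Path) -> None:
        write_table(self.rows.join(self.counts), path,
                    index_label="sequence")


def annotate_table(table: UniqueSequenceTable,
                   reference: PrecursorReference,
                   contaminants: Iterable[FastaRecord] = (),
                   max_mismatch: int = DEFAULT_MAX_MISMATCH,
                   max_end_shift: int = DEFAULT_MAX_END_SHIFT,
                   flank: int = FLANK_WINDOW) -> AnnotationResult:
    """Classify every unique sequence in the table."""
    retained, removed = remove_contaminants(table, contaminants)
    rows = []
    for seq in removed.counts.index:
        rows.append(AnnotationRow(seq, "contaminant"))
    for seq in retained.counts.index:
        hits = map_to_precursors(seq, reference, max_mismatch, max_end_shift)
        rows.append(classify(seq, hits, reference, flank))
    columns = ["class", "precursor", "offset", "mismatches", "end_shift",
               "assigned_id", "flank_start", "flank_end"]
    df = pd.DataFrame(
        [{
            "class": r.klass, "precursor": r.precursor, "offset": r.offset,
            "mismatches": r.mismatches, "end_shift": r.end_shift,
            "assigned_id": r.assigned_id, "flank_start": r.flank_start,
            "flank_end": r.flank_end,
        } for r in rows],
        index=pd.Index([r.sequence for r in rows], name="sequence"),
        columns=columns,
    )
    df = df.loc[table.counts.index]  # preserve table order
    return AnnotationResult(df, table.counts)
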