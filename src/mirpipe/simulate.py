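"""Synthetic references, reads, and cohorts with planted effects.

Everything downstream is testable offline: precursors are built as
stem + loop + reverse-complement so their folds satisfy the stem/length/
loop criteria by construction, reads are mature-arm inserts (optionally
end-shifted and mismatched) ligated to a 3' adapter, and cohorts carry a
planted linear effect of a marker on the pain-interference score.

Count noise is negative binomial with configurable dispersion
(var = mu + d * mu^2), collapsing to Poisson at d = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import MatureAnnotation, PrecursorRecord, PrecursorReference
from .seqio import FastaRecord, FastqRecord, revcomp

BASES = "ACGU"
CONTAMINANT_FAMILIES = ("rRNA", "tRNA", "snRNA", "snoRNA")
DEFAULT_ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"  # Illumina TruSeq small-RNA 3'
READ_QUALITY = 40

DEFAULT_INTERFERENCE_INTERCEPT = 2.0


@dataclass(frozen=True)
class SimulatedReference:
    precursors: tuple[PrecursorRecord, ...]
    contaminants: tuple[FastaRecord, ...]   # description holds the family

    def to_reference(self, arms: str = "both") -> PrecursorReference:
        """Expose the precursors for mapping.

        ``arms``: ``both`` keeps both annotated matures; ``alternate``
        keeps a single arm per precursor (5p for even indices, 3p for
        odd) so the unannotated arm yields novel candidates.
        """
        records = []
        for idx, rec in enumerate(self.precursors):
            if arms == "both":
                matures = rec.matures
            elif arms == "alternate":
                keep = "5p" if idx % 2 == 0 else "3p"
                matures = tuple(m for m in rec.matures if m.arm == keep)
            else:
                raise ValueError(f"unknown arms mode {arms!r}")
            records.append(PrecursorRecord(rec.id, rec.sequence, matures))
        return PrecursorReference(records)

    def mature_sequences(self) -> dict[str, str]:
        out = {}
        for rec in self.precursors:
            for m in rec.matures:
                out[m.name] = rec.sequence[m.start:m.end]
        return out


@dataclass(frozen=True)
class ReadSimConfig:
    adapter: str = DEFAULT_ADAPTER
    n_reads: int = 10_000
    fraction_junk: float = 0.05
    fraction_contaminant: float = 0.05
    fraction_novel_arm: float = 0.0
    end_variation_max: int = 0
    mismatch_rate: float = 0.0
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.fraction_junk + self.fraction_contaminant
              + self.fraction_novel_arm)
        if fr > 1:
            raise ValueError("fractions sum above 1")
        if self.end_variation_max > 2:
            raise ValueError("end_variation_max above 2")


@dataclass(frozen=True)
class CohortSimConfig:
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"no_sci": 20, "acute_sci": 20,
                                 "chronic_sci": 20})
    pain_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"no_sci": 0.0, "acute_sci": 0.5,
                                 "chronic_sci": 0.6})
    interference_slope: float = 0.0004
    interference_intercept: float = DEFAULT_INTERFERENCE_INTERCEPT
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("n_per_group entries must be >= 2")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _plant_mismatches(rng: np.random.Generator, seq: str, k: int) -> str:
    if k == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(k, len(chars)),
                           replace=False)
    for p in positions:
        options = [b for b in BASES if b != chars[p]]
        chars[p] = options[rng.integers(len(options))]
    return "".join(chars)


def generate_reference(n_precursors: int, n_contaminants: int,
                       seed: int) -> SimulatedReference:
    """Build hairpin precursors (stem + loop + reverse complement).

    Stems are 26-32 bp with at most 2 planted mismatches, loops 4-12 nt,
    mature arms 20-24 nt inside each stem arm — so every precursor folds
    with >= 16 stem pairs, hairpin length >= 50 and loop <= 20 by
    construction.
    """
    if n_precursors < 1:
        raise ValueError("n_precursors must be >= 1")
    rng = np.random.default_rng(seed)
    precursors = []
    for i in range(n_precursors):
        stem = int(rng.integers(26, 33))
        loop_len = int(rng.integers(4, 13))
        arm5 = _random_seq(rng, stem)
        loop = _random_seq(rng, loop_len)
        arm3 = _plant_mismatches(rng, revcomp(arm5), int(rng.integers(0, 3)))
        seq = arm5 + loop + arm3
        mat_len5 = int(rng.integers(20, 25))
        start5 = int(rng.integers(0, stem - mat_len5 + 1))
        mat_len3 = int(rng.integers(20, 25))
        start3 = stem + loop_len + int(rng.integers(0, stem - mat_len3 + 1))
        pid = f"pre-{i + 1}"
        precursors.append(PrecursorRecord(
            pid, seq,
            (MatureAnnotation(f"{pid}-5p", start5, start5 + mat_len5, "5p"),
             MatureAnnotation(f"{pid}-3p", start3, start3 + mat_len3, "3p"))))
    contaminants = []
    for i in range(n_contaminants):
        fam = CONTAMINANT_FAMILIES[i % len(CONTAMINANT_FAMILIES)]
        length = int(rng.integers(60, 121))
        contaminants.append(FastaRecord(
            f"contam-{fam}-{i + 1}", _random_seq(rng, length),
            f"family={fam}"))
    return SimulatedReference(tuple(precursors), tuple(contaminants))


def _nb_count(rng: np.random.Generator, mean: float,
              dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_sample_reads(reference: SimulatedReference,
                          expression: Mapping[str, float],
                          config: ReadSimConfig) -> list[FastqRecord]:
    """One sample's FASTQ records for the given expected mature counts.

    Non-junk, non-contaminant reads are mature-arm inserts with optional
    end variation (extended/trimmed using precursor context) and at most
    one planted internal mismatch, 3'-ligated to the adapter. Junk reads
    are homopolymer-rich; contaminant reads are substrings of contaminant
    records. An empty expression map yields junk/contaminant reads only.
    """
    rng = np.random.default_rng(config.seed)
    mature_seqs = reference.mature_sequences()
    mature_pos: dict[str, tuple[str, int, int]] = {}
    for rec in reference.precursors:
        for m in rec.matures:
            mature_pos[m.name] = (rec.sequence, m.start, m.end)
    unknown = set(expression) - set(mature_seqs)
    if unknown:
        raise ValueError(f"expression keys not in reference: {sorted(unknown)}")

    inserts: list[str] = []
    for mid in expression:  # caller-supplied order, deterministic
        pre, s, e = mature_pos[mid]
        n = _nb_count(rng, float(expression[mid]), config.dispersion)
        for _ in range(n):
            s2, e2 = s, e
            if config.end_variation_max > 0:
                s2 = s + int(rng.integers(-config.end_variation_max,
                                          config.end_variation_max + 1))
                e2 = e + int(rng.integers(-config.end_variation_max,
                                          config.end_variation_max + 1))
                s2 = max(0, min(s2, e - 1))
                e2 = min(len(pre), max(e2, s + 1))
            ins = pre[s2:e2]
            if config.mismatch_rate > 0 and rng.random() < config.mismatch_rate \
                    and len(ins) > 2:
                p = int(rng.integers(1, len(ins) - 1))   # internal only
                options = [b for b in BASES if b != ins[p]]
                ins = ins[:p] + options[rng.integers(len(options))] + ins[p + 1:]
            inserts.append(ins)

    n_junk = int(round(config.fraction_junk * config.n_reads))
    for _ in range(n_junk):
        length = int(rng.integers(18, 27))
        if rng.random() < 0.5:
            ins = BASES[rng.integers(4)] * length       # homopolymer
        else:
            major, minor = rng.choice(4, size=2, replace=False)
            ins = "".join(BASES[major] if rng.random() < 0.92
                          else BASES[minor] for _ in range(length))
        inserts.append(ins)

    n_cont = int(round(config.fraction_contaminant * config.n_reads))
    if n_cont and not reference.contaminants:
        raise ValueError("fraction_contaminant > 0 but no contaminants")
    for _ in range(n_cont):
        rec = reference.contaminants[rng.integers(len(reference.contaminants))]
        length = int(rng.integers(18, 27))
        start = int(rng.integers(0, len(rec.sequence) - length + 1))
        inserts.append(rec.sequence[start:start + length])

    rng.shuffle(inserts)
    records = []
    for i, ins in enumerate(inserts):
        seq = ins + config.adapter
        records.append(FastqRecord(
            f"read_{i + 1:06d}", seq, (READ_QUALITY,) * len(seq)))
    return records


def plant_expression(reference: SimulatedReference,
                     baseline: float,
                     log2fc: Mapping[str, float],
                     group: str,
                     affected_group: str) -> dict[str, float]:
    """Expected counts per mature id, with planted fold changes.

    Matures listed in ``log2fc`` are scaled by 2**lfc in
    ``affected_group`` only.
    """
    out = {}
    for mid in sorted(reference.mature_sequences()):
        mean = baseline
        if group == affected_group and mid in log2fc:
            mean = baseline * 2.0 ** log2fc[mid]
        out[mid] = mean
    return out


def simulate_cohort(config: CohortSimConfig,
                    marker_levels: Mapping[str, Mapping[str, float]],
                    driver: str | None = None,
                    groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Cohort table with a planted marker -> pain-interference effect.

    Pain-interference scores are intercept + slope x driver-marker level
    + Gaussian noise, clipped to [0, 10]. ``groups`` maps sample to group
    label; by default samples are assigned in order according to
    ``n_per_group``. Covariates are drawn from fixed marginals.
    """
    rng = np.random.default_rng(config.seed)
    samples = list(marker_levels)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate samples in marker_levels")
    if groups is None:
        labels = []
        for g, n in config.n_per_group.items():
            labels += [g] * n
        if len(labels) < len(samples):
            raise ValueError("n_per_group covers fewer samples than given")
        groups = dict(zip(samples, labels))
    if driver is None:
        first = next(iter(marker_levels.values()))
        driver = sorted(first)[0]

    rows = []
    for s in samples:
        g = groups[s]
        marker = dict(marker_levels[s])
        level = float(marker.get(driver, 0.0))
        pain = int(rng.random() < config.pain_prevalence.get(g, 0.0))
        interference = {}
        for dim in ("mood", "activities", "sleep"):
            val = (config.interference_intercept
                   + config.interference_slope * level
                   + rng.normal(0.0, config.noise_sd))
            interference[dim] = float(np.clip(val, 0.0, 10.0))
        sci = g != "no_sci"
        age = float(np.clip(rng.normal(38.0, 11.0), 18.0, 75.0))
        injury_duration = float(rng.uniform(3.0, 20.0)) if g == "chronic_sci" \
            else (float(rng.uniform(0.05, 0.25)) if g == "acute_sci" else np.nan)
        row = {
            "sample": s,
            "group": g,
            "neuropathic_pain": pain,
            "pain_intensity": float(np.clip(
                rng.normal(5.0, 2.0) if pain else rng.normal(1.0, 1.0),
                0.0, 10.0)),
            "interference_mood": interference["mood"],
            "interference_activities": interference["activities"],
            "interference_sleep": interference["sleep"],
            "male": int(rng.random() < 0.7),
            "age": age,
            "injury_duration": injury_duration,
            "age_at_injury": age - injury_duration if sci else np.nan,
            "opioid": int(rng.random() < 0.3) if sci else 0,
            "spasmolytic": int(rng.random() < 0.3) if sci else 0,
            "gabapentin": int(rng.random() < 0.25) if sci else 0,
            "antidepressant": int(rng.random() < 0.2),
            "nsaid": int(rng.random() < 0.3),
            "smoker": int(rng.random() < 0.25),
            "pack_years": float(rng.gamma(2.0, 4.0)) if rng.random() < 0.25
            else 0.0,
            "alcohol_grams": float(rng.gamma(2.0, 500.0)),
        }
        for mid in sorted(marker):
            row[mid] = float(marker[mid])
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
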