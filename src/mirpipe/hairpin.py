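"""Hairpin secondary-structure prediction and candidate criteria.

Folding uses a simplified per-pair energy model (GC -3.0, AU -2.0,
GU -1.0 kcal/mol; minimum hairpin loop of 3 nt) minimized by a
non-crossing dynamic program. The energy scale therefore belongs to this
model, not to a nearest-neighbor folder; the free-energy threshold is
configurable for that reason. Structures produced by an external folder
can be plugged in through :meth:`SecondaryStructure.from_dotbracket`
without touching feature extraction or criteria evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .seqio import as_rna

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

# Watson-Crick submodel: closed under reverse complementation, so folding
# a sequence and its reverse complement gives equal minimum energies.
# GU wobble breaks that symmetry (GU maps to AC, which cannot pair).
WATSON_CRICK_ENERGY = {k: v for k, v in PAIR_ENERGY.items()
                       if "U" not in k or "G" not in k}

MIN_LOOP = 3  # minimum unpaired nt enclosed by a pair

_ALLOWED = set("ACGUN")


def pair_energy(a: str, b: str,
                energies: dict[tuple[str, str], float] | None = None) -> float:
    """Energy of pairing bases a-b; 0.0 if they cannot pair (incl. N)."""
    return (PAIR_ENERGY if energies is None else energies).get((a, b), 0.0)


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing RNA secondary structure with its model energy."""

    sequence: str
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]
    energy: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")

    @property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @classmethod
    def from_dotbracket(cls, sequence: str, dotbracket: str,
                        energy: float | None = None) -> "SecondaryStructure":
        """Build from a Vienna-style dot-bracket string.

        When ``energy`` is None it is computed from the per-pair model, so
        hand-written or externally folded structures carry a consistent
        energy.
        """
        sequence = as_rna(sequence)
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for i, c in enumerate(dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket")
                pairs.append((stack.pop(), i))
            elif c != ".":
                raise ValueError(f"unexpected dot-bracket character {c!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket")
        pairs.sort()
        if energy is None:
            energy = sum(pair_energy(sequence[i], sequence[j])
                         for i, j in pairs)
        return cls(sequence, dotbracket, tuple(pairs), float(energy))


def fold(sequence: str,
         energies: dict[tuple[str, str], float] | None = None,
         ) -> SecondaryStructure:
    """Minimum-energy non-crossing structure under the per-pair model.

    Deterministic traceback: at equal energy a pairing is preferred over
    leaving the 5' base unpaired, and the 3'-most admissible partner wins,
    which extends nested stems outermost-first. ``energies`` overrides the
    default pair-energy table (e.g. ``WATSON_CRICK_ENERGY``).
    """
    seq = as_rna(sequence)
    n = len(seq)
    if not 10 <= n <= 200:
        raise ValueError(f"sequence length {n} outside [10, 200]")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    # E[i][j]: min energy of seq[i..j]; pairs (i,k) need k - i > MIN_LOOP.
    E = [[0.0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = pair_energy(seq[i], seq[k], energies)
                if e >= 0.0:
                    continue
                inner = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                rest = E[k + 1][j] if k + 1 <= j else 0.0
                cand = e + inner + rest
                if cand < best:
                    best = cand
            E[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = E[i][j]
        chosen = None
        for k in range(j, i + MIN_LOOP, -1):  # 3'-most partner first
            e = pair_energy(seq[i], seq[k], energies)
            if e >= 0.0:
                continue
            inner = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
            rest = E[k + 1][j] if k + 1 <= j else 0.0
            if e + inner + rest == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
            continue
        pairs.append((i, chosen))
        stack.append((i + 1, chosen - 1))
        if chosen + 1 <= j:
            stack.append((chosen + 1, j))

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return SecondaryStructure(seq, "".join(db), tuple(pairs), E[0][n - 1])


@dataclass(frozen=True)
class HairpinFeatures:
    """Quantities consumed by the 11 structural criteria."""

    stem_bp: int = 0
    largest_stem_bulge: int = 0
    hairpin_length: int = 0
    loop_length: int = 0
    mature_bp: int = 0
    mature_errors: int = 0
    largest_mature_bulge: int = 0
    biased_mature_bulges: int = 0
    biased_errors_one_mature_bulge: int = 0
    percent_mature_in_stem: float = 0.0


def _stem_chain(partner: dict[int, int],
                closing: tuple[int, int]) -> list[tuple[int, int]]:
    """Pairs of the stem ending at the hairpin-closing pair, inner→outer.

    The stem extends outward through bulges/interior loops and stops at a
    multiloop branch or the exterior.
    """
    chain = [closing]
    i, j = closing
    while True:
        # scan 5'-ward for the next paired base
        p = i - 1
        while p >= 0 and p not in partner:
            p -= 1
        if p < 0:
            break
        q = partner[p]
        if q <= j:          # p closes inside: not an enclosing pair
            break
        # every base between j and q must be unpaired (no branching)
        if any(x in partner for x in range(j + 1, q)):
            break
        chain.append((p, q))
        i, j = p, q
    return chain


def _bulge_events(chain: list[tuple[int, int]]) -> list[tuple[int, int, range, range]]:
    """Interior bulge events between consecutive stem pairs.

    Each event is (five_prime_run_len, three_prime_run_len, 5' range,
    3' range); only events with at least one unpaired nt are returned.
    """
    events = []
    for (i2, j2), (i1, j1) in zip(chain, chain[1:]):  # inner, outer
        run5 = range(i1 + 1, i2)
        run3 = range(j2 + 1, j1)
        if len(run5) or len(run3):
            events.append((len(run5), len(run3), run5, run3))
    return events


def extract_features(structure: SecondaryStructure,
                     mature: tuple[int, int]) -> HairpinFeatures:
    """Measure the dominant hairpin of ``structure`` around ``mature``.

    ``mature`` is a 0-based half-open interval. The dominant hairpin is the
    one whose stem span overlaps the mature placement most; with no overlap
    anywhere, the stem with the most base pairs. A structure without any
    pair yields all-zero features.
    """
    ms, me = mature
    if not (0 <= ms <= me <= len(structure.sequence)):
        raise ValueError("mature interval outside the sequence")
    partner = structure.partner
    if not partner:
        return HairpinFeatures()

    # hairpin loops: pairs enclosing no other paired base
    loops = []
    for i, j in structure.pairs:
        if not any(x in partner for x in range(i + 1, j)):
            loops.append((i, j))
    if not loops:
        return HairpinFeatures()

    candidates = []
    for closing in loops:
        chain = _stem_chain(partner, closing)
        (i_in, j_in), (i_out, j_out) = chain[0], chain[-1]
        span = set(range(i_out, i_in + 1)) | set(range(j_in, j_out + 1))
        overlap = len(span & set(range(ms, me)))
        candidates.append((overlap, len(chain), chain, span, closing))
    # most mature overlap, then longest stem, then 5'-most (deterministic)
    candidates.sort(key=lambda t: (-t[0], -t[1], t[4]))
    _, _, chain, span, closing = candidates[0]
    (i_in, j_in), (i_out, j_out) = chain[0], chain[-1]

    events = _bulge_events(chain)
    largest_stem_bulge = max(
        (max(r5, r3) for r5, r3, _, _ in events), default=0
    )

    mature_set = set(range(ms, me))
    mature_len = me - ms
    mature_bp = sum(1 for x in mature_set if x in partner)
    mature_errors = mature_len - mature_bp

    # bulge events touching the mature region
    largest_mature_bulge = 0
    biased_mature_bulges = 0
    biased_errors_one = 0
    for r5, r3, run5, run3 in events:
        in5 = len(mature_set & set(run5))
        in3 = len(mature_set & set(run3))
        if in5 == 0 and in3 == 0:
            continue
        largest_mature_bulge = max(largest_mature_bulge, r5, r3)
        biased = (r5 == 0) != (r3 == 0)  # all unpaired nt on one strand
        if biased:
            biased_mature_bulges += 1
            biased_errors_one = max(biased_errors_one, r5, r3)

    percent = 100.0 * len(mature_set & span) / mature_len if mature_len else 0.0

    return HairpinFeatures(
        stem_bp=len(chain),
        largest_stem_bulge=largest_stem_bulge,
        hairpin_length=j_out - i_out + 1,
        loop_length=j_in - i_in - 1,
        mature_bp=mature_bp,
        mature_errors=mature_errors,
        largest_mature_bulge=largest_mature_bulge,
        biased_mature_bulges=biased_mature_bulges,
        biased_errors_one_mature_bulge=biased_errors_one,
        percent_mature_in_stem=percent,
    )


@dataclass(frozen=True)
class CriteriaThresholds:
    """The 11 printed thresholds for novel-candidate acceptance.

    Defaults match the standard screening thresholds; ``c3_max_free_energy`` applies to
    this package's simplified energy scale when used with :func:`fold`.
    """

    c1_max_stem_bulge: int = 12
    c2_min_stem_bp: int = 16
    c3_max_free_energy: float = -15.0
    c4_min_hairpin_length: int = 50
    c5_max_loop_length: int = 20
    c6_max_mature_bulge: int = 8
    c7_max_biased_errors_one_bulge: int = 4
    c8_max_biased_mature_bulges: int = 2
    c9_max_mature_errors: int = 7
    c10_min_mature_bp: int = 12
    c11_min_percent_mature_in_stem: float = 80.0


@dataclass(frozen=True)
class CriteriaReport:
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    c8: bool
    c9: bool
    c10: bool
    c11: bool
    overall: bool = field(default=False)

    def flags(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "overall"}


def evaluate_criteria(features: HairpinFeatures, energy: float,
                      thresholds: CriteriaThresholds = CriteriaThresholds(),
                      ) -> CriteriaReport:
    """Apply the 11 criteria; overall pass iff every one holds.

    All comparisons are boundary-inclusive in the printed direction.
    """
    t = thresholds
    f = features
    flags = dict(
        c1=f.largest_stem_bulge <= t.c1_max_stem_bulge,
        c2=f.stem_bp >= t.c2_min_stem_bp,
        c3=energy <= t.c3_max_free_energy,
        c4=f.hairpin_length >= t.c4_min_hairpin_length,
        c5=f.loop_length <= t.c5_max_loop_length,
        c6=f.largest_mature_bulge <= t.c6_max_mature_bulge,
        c7=f.biased_errors_one_mature_bulge <= t.c7_max_biased_errors_one_bulge,
        c8=f.biased_mature_bulges <= t.c8_max_biased_mature_bulges,
        c9=f.mature_errors <= t.c9_max_mature_errors,
        c10=f.mature_bp >= t.c10_min_mature_bp,
        c11=f.percent_mature_in_stem >= t.c11_min_percent_mature_in_stem,
    )
    return CriteriaReport(**flags, overall=all(flags.values()))


def classify_candidate(sequence: str, mature: tuple[int, int],
                       thresholds: CriteriaThresholds = CriteriaThresholds(),
                       ) -> tuple[SecondaryStructure, HairpinFeatures, CriteriaReport]:
    """Fold a candidate flank window and evaluate all criteria."""
    st = fold(sequence)
    feats = extract_features(st, mature)
    report = evaluate_criteria(feats, st.energy, thresholds)
    return st, feats, report
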