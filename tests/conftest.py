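"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: folding
is checked against full enumeration of non-crossing structures (small n)
and against a memoized recursion using a different interval decomposition
(last base instead of first base); alignment against a quadratic scan.
"""

from __future__ import annotations

import functools

import pytest

from mirpipe.hairpin import MIN_LOOP, pair_energy

# ---------------------------------------------------------------------------
# folding oracles


def enumerate_structures(seq: str):
    """Yield every valid non-crossing pair set (exponential; tiny n only)."""
    n = len(seq)

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield ()
            return
        i = positions[0]
        # i unpaired
        for rest in rec(positions[1:]):
            yield rest
        # i paired with some admissible j
        for idx, j in enumerate(positions[1:], start=1):
            if j - i <= MIN_LOOP:
                continue
            if pair_energy(seq[i], seq[j]) >= 0.0:
                continue
            inside = tuple(p for p in positions[1:idx])
            outside = tuple(p for p in positions[idx + 1:])
            # non-crossing: inside and outside close independently
            for a in rec(inside):
                for b in rec(outside):
                    yield ((i, j),) + a + b

    yield from rec(tuple(range(n)))


def enumeration_min_energy(seq: str) -> float:
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = sum(pair_energy(seq[i], seq[j]) for i, j in pairs)
        best = min(best, e)
    return best


def memoized_min_energy(seq: str) -> float:
    """Min energy via recursion on the LAST base of each interval."""

    @functools.lru_cache(maxsize=None)
    def E(i: int, j: int) -> float:
        if j - i <= MIN_LOOP:
            return 0.0
        best = E(i, j - 1)                      # j unpaired
        for k in range(i, j - MIN_LOOP):        # k pairs with j
            e = pair_energy(seq[k], seq[j])
            if e >= 0.0:
                continue
            left = E(i, k - 1) if k - 1 >= i else 0.0
            inner = E(k + 1, j - 1)
            best = min(best, e + left + inner)
        return best

    return E(0, len(seq) - 1) if seq else 0.0


# ---------------------------------------------------------------------------
# alignment oracle


def brute_force_hits(sequence: str, precursors: list[tuple[str, str]],
                     max_mismatch: int) -> list[tuple[str, int, int]]:
    """(precursor id, offset, mismatches) for every admissible placement."""
    out = []
    L = len(sequence)
    for pid, pre in precursors:
        for off in range(len(pre) - L + 1):
            mm = sum(a != b for a, b in zip(sequence, pre[off:off + L]))
            if mm <= max_mismatch:
                out.append((pid, off, mm))
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_reference():
    from mirpipe.simulate import generate_reference
    return generate_reference(5, 3, seed=42)


@pytest.fixture()
def random_sequences():
    import numpy as np

    def make(n: int, length: int, seed: int) -> list[str]:
        rng = np.random.default_rng(seed)
        return ["".join(rng.choice(list("ACGU"), size=length))
                for _ in range(n)]

    return make
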