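"""Independent brute-force oracles used by the property and acceptance tests.

These deliberately share no code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_best_overlap(a: str, b: str, min_overlap: int, min_identity: float):
    """Exhaustive suffix(a)-prefix(b) scan with mismatch-only scoring.

    Returns (length, a_suffix_start, identity) of the best candidate by
    (score, length), or None.
    """
    best = None
    best_key = None
    for length in range(min_overlap, min(len(a), len(b)) + 1):
        mism = sum(x != y for x, y in zip(a[-length:], b[:length]))
        ident = (length - mism) / length
        if ident < min_identity:
            continue
        key = (ident * length, length)
        if best_key is None or key > best_key:
            best_key = key
            best = (length, len(a) - length, ident)
    return best


def overlap_pair(rng: np.random.Generator, max_len: int = 200):
    """A random read pair: half the time with a planted noisy overlap."""
    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    if rng.random() < 0.5:
        return rand(int(rng.integers(30, max_len))), rand(int(rng.integers(30, max_len)))
    ov = int(rng.integers(20, 120))
    shared = rand(ov)
    noisy = list(shared)
    for _ in range(int(rng.integers(0, 4))):
        k = int(rng.integers(0, ov))
        noisy[k] = "ACGT"[int(rng.integers(0, 4))]
    a = rand(int(rng.integers(0, max_len - ov))) + shared
    b = "".join(noisy) + rand(int(rng.integers(0, max_len - ov)))
    return a[:max_len], b[:max_len]


def brute_force_rbh(hits_ab, hits_ba, cutoff):
    """Double-loop reciprocal-best-hit oracle over raw hit rows."""
    def best_for(query, hits):
        rows = [h for h in hits if h.query_id == query and h.evalue < cutoff]
        if not rows:
            return None
        best = rows[0]
        for h in rows[1:]:
            if (h.evalue, -h.bitscore) < (best.evalue, -best.bitscore):
                best = h
        return best.subject_id

    pairs = set()
    for a in {h.query_id for h in hits_ab}:
        b = best_for(a, hits_ab)
        if b is not None and best_for(b, hits_ba) == a:
            pairs.add((a, b))
    return pairs
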