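"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force SSR oracle, written independently of ssrexp.miner:
# for every (start, motif size) it copies out the unit, counts explicit
# unit copies by string comparison, and keeps only left/right-maximal,
# primitive-unit runs meeting the per-size minimum.


def naive_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0:
            if all(unit[k] == unit[k % d] for k in range(len(unit))):
                return False
    return True


def oracle_find_ssrs(seq: str, min_reps=(15, 8, 5, 4, 3, 3)) -> set[tuple]:
    """All maximal perfect repeats as (start, motif, repeat_count), 1-based."""
    n = len(seq)
    found = set()
    for size in range(1, 7):
        for i in range(0, n - size):
            unit = seq[i : i + size]
            if "N" in unit or not naive_primitive(unit):
                continue
            # left maximality: the period must break just before i
            if i >= 1 and i - 1 + size < n:
                if seq[i - 1] != "N" and seq[i - 1] == seq[i - 1 + size]:
                    continue
            # extend right base by base while the period holds
            j = i + size
            while j < n and seq[j] != "N" and seq[j] == seq[j - size]:
                j += 1
            count = (j - i) // size
            if count >= max(min_reps[size - 1], 2):
                found.add((i + 1, unit, count))
    return found


def repeat_rich_sequence(rng: np.random.Generator, length: int,
                         copy_prob: float = 0.55, n_prob: float = 0.002) -> str:
    """Random DNA with a back-copy process that spawns tandem repeats."""
    bases = "ACGT"
    out: list[str] = []
    period = 1
    for _ in range(length):
        if rng.random() < n_prob:
            out.append("N")
            continue
        if out and rng.random() < copy_prob:
            if rng.random() < 0.1 or period > len(out):
                period = int(rng.integers(1, 7))
            if period <= len(out) and out[-period] != "N":
                out.append(out[-period])
                continue
        out.append(bases[rng.integers(4)])
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240417)
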