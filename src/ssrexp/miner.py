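"""Perfect microsatellite (SSR) detection and motif canonicalization.

A simple sequence repeat (SSR, microsatellite) is an uninterrupted tandem
repeat of a 1-6 bp unit.  Detection follows the MISA conventions used in
transcriptome SSR surveys: per-size minimum repeat counts (default
15, 8, 5, 4, 3, 3 for mono- through hexanucleotides), maximal runs, the
repeat unit must be primitive (not itself a repetition of a shorter unit),
and trailing partial units are truncated so that the tract length is an
exact multiple of the unit size.

Motifs are folded into standardized classes: the class representative of a
motif is the lexicographically smallest string over all rotations of the
motif and all rotations of its reverse complement, the usual "AG/CT"-style
pairing.  The actual motif as read on the transcript strand is kept
alongside the class, because strand-specific effects are of interest
downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

MAX_MOTIF_SIZE = 6

#: MISA-style minimum repeat counts for motif sizes 1..6.
DEFAULT_MIN_REPEATS: tuple[int, ...] = (15, 8, 5, 4, 3, 3)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = set("ACGTN")

#: Columns of the miner TSV.
SSR_COLUMNS = [
    "transcript_id",
    "ssr_index",
    "motif",
    "canonical_motif",
    "motif_size",
    "repeat_count",
    "start",
    "end",
    "tract_length",
    "compound_id",
]


@dataclass(frozen=True)
class MinerCriteria:
    """Search thresholds for the SSR scan.

    Parameters
    ----------
    min_repeats_by_size
        Minimum repeat count for each motif size 1..6.
    max_interruption_bp
        Largest gap (in bp) allowed between consecutive SSRs of one
        compound SSR.  0 means strictly adjacent ("without interrupted
        bases"); MISA's conventional value for interoperability is 100.
    """

    min_repeats_by_size: tuple[int, ...] = DEFAULT_MIN_REPEATS
    max_interruption_bp: int = 0

    def __post_init__(self) -> None:
        if len(self.min_repeats_by_size) != MAX_MOTIF_SIZE:
            raise ValueError("min_repeats_by_size must have 6 entries (sizes 1-6)")
        if any(int(m) < 1 for m in self.min_repeats_by_size):
            raise ValueError("all minimum repeat counts must be >= 1")
        if self.max_interruption_bp < 0:
            raise ValueError("max_interruption_bp must be >= 0")


@dataclass
class SSRRecord:
    """One perfect SSR on a transcript; coordinates are 1-based inclusive."""

    transcript_id: str
    motif: str
    canonical_motif: str
    motif_size: int
    repeat_count: int
    start: int
    end: int
    tract_length: int
    compound_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tract_length != self.motif_size * self.repeat_count:
            raise ValueError("tract_length must equal motif_size * repeat_count")
        if self.end - self.start + 1 != self.tract_length:
            raise ValueError("end - start + 1 must equal tract_length")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonicalize_motif(motif: str) -> str:
    """Standardized class representative of a primitive motif.

    The representative is the lexicographically smallest string among all
    rotations of the motif and all rotations of its reverse complement;
    e.g. ``GA -> AG``, ``TTC -> AAG``, ``ACTTGC -> AAGTGC``.  Idempotent and
    invariant under rotation and reverse complementation of the input.
    """
    m = motif.upper()
    if not m or len(m) > MAX_MOTIF_SIZE:
        raise ValueError(f"motif must be 1-{MAX_MOTIF_SIZE} bp, got {motif!r}")
    if any(c not in "ACGT" for c in m):
        raise ValueError(f"motif must contain only A/C/G/T, got {motif!r}")
    if not is_primitive(m):
        raise ValueError(f"motif must be primitive, got {motif!r}")
    return min(_rotations(m) + _rotations(reverse_complement(m)))


def count_canonical_classes(motif_size: int) -> int:
    """Number of standardized motif classes for a given unit size.

    Computed by exhaustive enumeration of all primitive motifs of that size
    grouped under rotation + reverse-complement equivalence (2 for
    mononucleotides, 4 for dinucleotides, 10 for trinucleotides, ...).
    """
    if not 1 <= motif_size <= MAX_MOTIF_SIZE:
        raise ValueError(f"motif_size must be in 1-{MAX_MOTIF_SIZE}")
    classes = set()
    for tup in product("ACGT", repeat=motif_size):
        m = "".join(tup)
        if is_primitive(m):
            classes.add(canonicalize_motif(m))
    return len(classes)


def enumerate_canonical_classes(motif_size: int) -> list[str]:
    """Sorted class representatives of all primitive motifs of one size."""
    if not 1 <= motif_size <= MAX_MOTIF_SIZE:
        raise ValueError(f"motif_size must be in 1-{MAX_MOTIF_SIZE}")
    classes = {
        canonicalize_motif("".join(tup))
        for tup in product("ACGT", repeat=motif_size)
        if is_primitive("".join(tup))
    }
    return sorted(classes)


def find_perfect_ssrs(
    sequence: str,
    criteria: MinerCriteria | None = None,
    transcript_id: str = "",
) -> list[SSRRecord]:
    """Scan one sequence for every maximal perfect SSR meeting the criteria.

    Runs are reported at the smallest primitive unit that meets its size
    minimum (a mono-run is never double-reported as a di/tri/... run,
    because the longer unit would not be primitive).  Runs are broken at
    any ``N``.  Trailing partial units are truncated.  Records are sorted
    by start position; records of the same motif never overlap, records of
    different motifs may (an A-run can absorb the first A of a following
    AT-run).
    """
    if criteria is None:
        criteria = MinerCriteria()
    seq = sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            raise ValueError(f"non-IUPAC character {ch!r} at position {pos}")

    records: list[SSRRecord] = []
    for segment in re.finditer("[ACGT]+", seq):
        seg = segment.group()
        off = segment.start()  # 0-based offset of segment in seq
        length = len(seg)
        for size in range(1, MAX_MOTIF_SIZE + 1):
            min_rep = max(int(criteria.min_repeats_by_size[size - 1]), 2)
            if length < size * min_rep:
                continue
            j = 0
            limit = length - size
            while j < limit:
                if seg[j] != seg[j + size]:
                    j += 1
                    continue
                run_start = j
                while j < limit and seg[j] == seg[j + size]:
                    j += 1
                # matches hold on [run_start, j-1]; run spans run_start..j-1+size
                run_bp = (j - 1) - run_start + 1 + size
                count = run_bp // size
                if count >= min_rep:
                    unit = seg[run_start : run_start + size]
                    if is_primitive(unit):
                        start = off + run_start + 1
                        end = start + count * size - 1
                        records.append(
                            SSRRecord(
                                transcript_id=transcript_id,
                                motif=unit,
                                canonical_motif=canonicalize_motif(unit),
                                motif_size=size,
                                repeat_count=count,
                                start=start,
                                end=end,
                                tract_length=count * size,
                            )
                        )
    records.sort(key=lambda r: (r.start, r.motif_size))
    return records


def find_compound_ssrs(
    records: Sequence[SSRRecord],
    criteria: MinerCriteria | None = None,
    on_overlap: str = "error",
) -> list[SSRRecord]:
    """Group adjacent SSRs of one transcript into compound SSRs.

    A compound SSR is a maximal chain of >= 2 records in which every
    consecutive pair is separated by at most ``max_interruption_bp`` bases
    (default 0: no interrupting bases).  Member records stay in the flat
    SSR list; they are returned with a shared ``compound_id``.

    Input must be sorted by start and non-overlapping.  With
    ``on_overlap="chain"`` records sharing bases (possible for different
    motifs) are tolerated and treated as adjacent, which is the compound
    convention used by the pipeline.
    """
    if criteria is None:
        criteria = MinerCriteria()
    if on_overlap not in ("error", "chain"):
        raise ValueError("on_overlap must be 'error' or 'chain'")
    out = [replace(r, compound_id=None) for r in records]
    if not out:
        return out
    tids = {r.transcript_id for r in out}
    if len(tids) > 1:
        raise ValueError("records must come from a single transcript")
    tid = out[0].transcript_id

    chains: list[list[int]] = [[0]]
    for i in range(1, len(out)):
        prev, cur = out[i - 1], out[i]
        if cur.start < prev.start:
            raise ValueError("records must be sorted by start position")
        gap = cur.start - prev.end - 1
        if gap < 0 and on_overlap == "error":
            raise ValueError(
                f"overlapping records at {prev.start}-{prev.end} and "
                f"{cur.start}-{cur.end}"
            )
        if gap <= criteria.max_interruption_bp:
            chains[-1].append(i)
        else:
            chains.append([i])

    n_compound = 0
    for chain in chains:
        if len(chain) >= 2:
            n_compound += 1
            cid = f"{tid}|c{n_compound}" if tid else f"c{n_compound}"
            for i in chain:
                out[i] = replace(out[i], compound_id=cid)
    return out


def mine_sequences(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    criteria: MinerCriteria | None = None,
) -> pd.DataFrame:
    """Mine a set of sequences and return the miner table (one row per SSR)."""
    if criteria is None:
        criteria = MinerCriteria()
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    rows = []
    for tid, seq in items:
        recs = find_perfect_ssrs(seq, criteria, transcript_id=tid)
        recs = find_compound_ssrs(recs, criteria, on_overlap="chain")
        for idx, r in enumerate(recs, start=1):
            rows.append(
                (
                    r.transcript_id,
                    idx,
                    r.motif,
                    r.canonical_motif,
                    r.motif_size,
                    r.repeat_count,
                    r.start,
                    r.end,
                    r.tract_length,
                    r.compound_id if r.compound_id is not None else "",
                )
            )
    return pd.DataFrame(rows, columns=SSR_COLUMNS)


def read_fasta(path) -> dict[str, str]:
    """Read a (wrapped or unwrapped) multi-record FASTA into id -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def mine_fasta(path, criteria: MinerCriteria | None = None) -> pd.DataFrame:
    return mine_sequences(read_fasta(path), criteria)


def write_ssr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ssr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    df["compound_id"] = df.get("compound_id", pd.Series(dtype=str)).fillna("")
    return df
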