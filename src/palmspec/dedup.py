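"""Quality-aware PCR-duplicate removal for paired-end reads.

Mates are concatenated and two concatenated reads of equal length are
duplicates when the number of mismatching positions at which *both* bases
have quality >= 7 is at most max(1, floor(L / 200)). Duplicate pairs are
clustered by single linkage; the member with the highest mean quality over
both mates is retained (ties broken by read id, ascending bytewise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReadPair",
    "DedupReport",
    "concat_pair",
    "allowed_mismatches",
    "is_duplicate",
    "dedup",
    "read_paired_fastq",
    "write_paired_fastq",
]

DEFAULT_QUAL_FLOOR = 7
DEFAULT_MISMATCH_RATE = 1.0 / 200.0


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        for mate, (seq, qual) in enumerate(
            ((self.seq1, self.qual1), (self.seq2, self.qual2)), start=1
        ):
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {self.id!r} mate {mate}: sequence and quality lengths differ"
                )
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"read {self.id!r} mate {mate}: bad bases {bad}")

    def mean_quality(self) -> float:
        quals = list(self.qual1) + list(self.qual2)
        return float(np.mean(quals)) if quals else 0.0


@dataclass
class DedupReport:
    clusters: list[dict]  # {"members": [ids], "retained": id}
    n_input: int
    n_retained: int
    n_removed: int


def concat_pair(pair: ReadPair) -> tuple[str, np.ndarray]:
    """Concatenated sequence and qualities of the two mates, mate1 first."""
    seq = pair.seq1 + pair.seq2
    qual = np.fromiter(
        list(pair.qual1) + list(pair.qual2), dtype=np.int16, count=len(seq)
    )
    return seq, qual


def allowed_mismatches(length: int, mismatch_rate: float = DEFAULT_MISMATCH_RATE) -> int:
    """Mismatch allowance: max(1, floor(L * rate)) — one per 200 bp by default."""
    return max(1, int(length * mismatch_rate))


def is_duplicate(
    seq_a: str,
    qual_a: np.ndarray,
    seq_b: str,
    qual_b: np.ndarray,
    qual_floor: int = DEFAULT_QUAL_FLOOR,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
) -> bool:
    """Duplicate test on two concatenated reads.

    Unequal lengths are never duplicates. Mismatches where either base has
    quality < ``qual_floor`` or is N carry no evidence and are ignored.
    """
    if len(seq_a) != len(seq_b):
        return False
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    diff = a != b
    informative = (
        diff
        & (qual_a >= qual_floor)
        & (qual_b >= qual_floor)
        & (a != b"N")
        & (b != b"N")
    )
    return int(informative.sum()) <= allowed_mismatches(len(seq_a), mismatch_rate)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def dedup(
    pairs: Sequence[ReadPair],
    qual_floor: int = DEFAULT_QUAL_FLOOR,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    bucket: bool = False,
) -> tuple[list[ReadPair], DedupReport]:
    """Cluster duplicates and retain one pair per cluster.

    Candidate comparison is all-pairs within equal-length groups (exact).
    ``bucket=True`` additionally splits each length group by the first 16
    raw bases of the concatenation — a fast approximation that can split a
    true family when an allowed mismatch falls inside the prefix.
    """
    concat = [concat_pair(p) for p in pairs]
    uf = _UnionFind(len(pairs))

    groups: dict[tuple, list[int]] = {}
    for i, (seq, _q) in enumerate(concat):
        key: tuple = (len(seq),)
        if bucket:
            key = (len(seq), seq[:16])
        groups.setdefault(key, []).append(i)

    for members in groups.values():
        for a_pos, i in enumerate(members):
            seq_i, q_i = concat[i]
            for j in members[a_pos + 1 :]:
                if uf.find(i) == uf.find(j):
                    continue
                seq_j, q_j = concat[j]
                if is_duplicate(seq_i, q_i, seq_j, q_j, qual_floor, mismatch_rate):
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(pairs)):
        clusters.setdefault(uf.find(i), []).append(i)

    retained: list[ReadPair] = []
    cluster_records: list[dict] = []
    for members in clusters.values():
        # highest mean quality wins; ties -> smallest id bytewise
        best = min(members, key=lambda i: (-pairs[i].mean_quality(), pairs[i].id))
        retained.append(pairs[best])
        cluster_records.append(
            {
                "members": sorted(pairs[i].id for i in members),
                "retained": pairs[best].id,
            }
        )
    order = {p.id: k for k, p in enumerate(pairs)}
    retained.sort(key=lambda p: order[p.id])
    report = DedupReport(
        clusters=cluster_records,
        n_input=len(pairs),
        n_retained=len(retained),
        n_removed=len(pairs) - len(retained),
    )
    return retained, report


# ------------------------------------------------------------------- FASTQ IO


def read_paired_fastq(path1: str, path2: str) -> list[ReadPair]:
    """Load mate pairs from two Phred+33 FASTQ files, matched by order.

    Record-count or id mismatches raise, naming the offending record.
    """
    recs1 = list(SeqIO.parse(path1, "fastq"))
    recs2 = list(SeqIO.parse(path2, "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(
            f"mate files differ in record count: {len(recs1)} vs {len(recs2)}"
        )
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        base1 = r1.id.removesuffix("/1")
        base2 = r2.id.removesuffix("/2")
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
        pairs.append(
            ReadPair(
                id=base1,
                seq1=str(r1.seq),
                seq2=str(r2.seq),
                qual1=r1.letter_annotations["phred_quality"],
                qual2=r2.letter_annotations["phred_quality"],
            )
        )
    return pairs


def write_paired_fastq(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    def _fq(handle, rid: str, seq: str, qual: Sequence[int]) -> None:
        handle.write(f"@{rid}\n{seq}\n+\n")
        handle.write("".join(chr(q + 33) for q in qual) + "\n")

    with open(path1, "w") as h1, open(path2, "w") as h2:
        for p in pairs:
            _fq(h1, p.id + "/1", p.seq1, p.qual1)
            _fq(h2, p.id + "/2", p.seq2, p.qual2)
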