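"""Large-repeat detection and quadripartite partition of plastomes.

The canonical plastome is a circle tiled by four regions: a large and a
small single-copy region (LSC, SSC) separated by two copies of a large
repeat.  The two copies may lie on opposite strands (inverted repeat,
IR — the usual arrangement) or on the same strand (direct repeat, DR).
Detection is seed-and-extend over exact k-mer matches of the sequence
against itself and its reverse complement; an all-pairs dynamic-
programming oracle cross-checks it in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from plastevol.io import PlastomeRecord

__all__ = [
    "RepeatPair",
    "RegionPartition",
    "RegionStats",
    "find_large_repeat",
    "classify_orientation",
    "partition_regions",
    "region_stats",
    "stats_table",
]


@dataclass(frozen=True)
class RepeatPair:
    """The two copies of the large repeat (0-based half-open intervals)."""

    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    orientation: str  # "inverted" | "direct"
    identity: float

    def __post_init__(self) -> None:
        if self.orientation not in ("inverted", "direct"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        la = self.copy_a[1] - self.copy_a[0]
        lb = self.copy_b[1] - self.copy_b[0]
        if la != lb:
            raise ValueError(f"repeat copies of unequal length: {la} vs {lb}")
        if la <= 0:
            raise ValueError("empty repeat copy")
        if not (self.copy_a[1] <= self.copy_b[0] or self.copy_b[1] <= self.copy_a[0]):
            raise ValueError("repeat copies overlap")

    @property
    def length(self) -> int:
        return self.copy_a[1] - self.copy_a[0]


@dataclass(frozen=True)
class RegionPartition:
    """LSC / SSC / repeat tiling of the circle.

    Intervals are (start, end) on the linearized sequence; an interval
    with start > end wraps through the origin.  ``has_repeat`` is False
    for the degenerate single-region partition of a genome without a
    large repeat.
    """

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    repeat: RepeatPair | None
    genome_length: int
    has_repeat: bool = True

    @property
    def lsc_length(self) -> int:
        if not self.has_repeat:
            return self.genome_length
        return (self.lsc[1] - self.lsc[0]) % self.genome_length

    @property
    def ssc_length(self) -> int:
        if not self.has_repeat:
            return 0
        return (self.ssc[1] - self.ssc[0]) % self.genome_length

    def __post_init__(self) -> None:
        if self.has_repeat:
            total = self.lsc_length + self.ssc_length + 2 * self.repeat.length
            if total != self.genome_length:
                raise ValueError(
                    f"regions do not tile the circle: LSC {self.lsc_length} + SSC "
                    f"{self.ssc_length} + 2x{self.repeat.length} != {self.genome_length}"
                )
            if self.lsc_length < self.ssc_length:
                raise ValueError("LSC must be the longer single-copy arc")


@dataclass
class RegionStats:
    """Table-style per-region summary of one plastome."""

    taxon: str
    total_length: int
    repeat_length: int
    lsc_length: int
    ssc_length: int
    gc_total: float
    gc_repeat: float
    gc_lsc: float
    gc_ssc: float
    n_genes: int
    n_protein: int
    n_rrna: int
    n_trna: int
    n_introns: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# repeat detection


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _merge_runs(positions: list[tuple[int, int]], k: int, max_gap: int = 50):
    """Merge collinear seed pairs (i, j) sharing a diagonal into runs."""
    runs = []  # (i_start, i_end_exclusive_of_kmer, j_start)
    positions.sort()
    cur = None
    for i, j in positions:
        if cur is not None and i - cur[1] <= max_gap and j - (cur[1] - cur[0] + cur[2]) == i - cur[1]:
            cur = (cur[0], i + k, cur[2])
        else:
            if cur is not None:
                runs.append(cur)
            cur = (i, i + k, j)
    if cur is not None:
        runs.append(cur)
    return runs


def _extend(seq_a: str, seq_b: str, a0: int, a1: int, b0: int, drop: int = 50):
    """X-drop extension of an aligned gap-free pair.

    seq_a[a0:a1] aligns to seq_b[b0:b0+(a1-a0)].  Extends both
    directions scoring +1 per match and -3 per mismatch (N counts as a
    mismatch), stops once the running score falls ``drop`` below its
    maximum, and trims back to the best-scoring endpoint.
    """
    n_a, n_b = len(seq_a), len(seq_b)
    # right extension
    ra, rb = a1, b0 + (a1 - a0)
    score = best = 0
    best_ra = ra
    while ra < n_a and rb < n_b and best - score <= drop:
        score += 1 if (seq_a[ra] == seq_b[rb] and seq_a[ra] != "N") else -3
        ra += 1
        rb += 1
        if score > best:
            best = score
            best_ra = ra
    # left extension
    la, lb = a0, b0
    score = best = 0
    best_la = la
    while la > 0 and lb > 0 and best - score <= drop:
        score += 1 if (seq_a[la - 1] == seq_b[lb - 1] and seq_a[la - 1] != "N") else -3
        la -= 1
        lb -= 1
        if score > best:
            best = score
            best_la = la
    new_b0 = b0 - (a0 - best_la)
    return best_la, best_ra, new_b0


def _identity(seq_a: str, seq_b: str) -> float:
    match = sum(1 for x, y in zip(seq_a, seq_b) if x == y and x != "N")
    return match / max(1, len(seq_a))


def find_large_repeat(
    record: PlastomeRecord,
    min_len: int = 1000,
    min_identity: float = 0.98,
    k: int = 21,
    drop: int = 50,
) -> RepeatPair | None:
    """Locate the highest-scoring pair of large near-exact repeats.

    Scans exact k-mer matches of the genome against itself (direct
    candidates) and against its reverse complement (inverted
    candidates), merges collinear seeds, extends them with a
    mismatch-tolerant drop-off, and returns the best non-overlapping
    pair of length >= ``min_len`` and identity >= ``min_identity`` — or
    ``None`` when the genome has no large repeat.
    """
    seq = record.sequence
    n = len(seq)
    if n <= 2 * min_len:
        raise ValueError(f"{record.id}: sequence too short for min_len={min_len}")

    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmers.setdefault(seq[i : i + k], []).append(i)

    candidates: list[RepeatPair] = []

    # direct: same-strand matches at distinct positions
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        if len(positions) > 25:  # low-complexity seed, skip
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                by_diag.setdefault(j - i, []).append((i, j))
    for diag, pos in by_diag.items():
        if len(pos) * k < min_len // 2:
            continue
        for i0, i1, j0 in _merge_runs(pos, k):
            if i1 - i0 < min_len // 2:
                continue
            a0, a1, b0 = _extend(seq, seq, i0, i1, j0, drop)
            length = a1 - a0
            b1 = b0 + length
            if length < min_len or b0 < a1:  # overlapping copies
                continue
            ident = _identity(seq[a0:a1], seq[b0:b1])
            if ident >= min_identity:
                candidates.append(RepeatPair((a0, a1), (b0, b1), "direct", ident))

    # inverted: match against reverse complement.  A forward seed at j
    # matching the reverse complement at i satisfies i - j = const along
    # a collinear inverted repeat, so group by that difference.
    rc = _revcomp(seq)
    by_anti: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - k + 1):
        kmer = rc[i : i + k]
        hits = kmers.get(kmer)
        if not hits or len(hits) > 25:
            continue
        for j in hits:
            # rc position i corresponds to forward interval [n-i-k, n-i)
            fwd_start = n - i - k
            if fwd_start <= j:
                continue  # count each pair once, second copy downstream
            by_anti.setdefault(i - j, []).append((j, i))  # (fwd pos of copyA, rc pos)
    for anti, pos in by_anti.items():
        if len(pos) * k < min_len // 2:
            continue
        for i0, i1, j0 in _merge_runs(pos, k):
            if i1 - i0 < min_len // 2:
                continue
            a0, a1, b0rc = _extend(seq, rc, i0, i1, j0, drop)
            length = a1 - a0
            b1rc = b0rc + length
            # map rc interval back to forward coordinates
            b0, b1 = n - b1rc, n - b0rc
            if length < min_len or b0 < a1:
                continue
            ident = _identity(seq[a0:a1], rc[b0rc:b1rc])
            if ident >= min_identity:
                candidates.append(RepeatPair((a0, a1), (b0, b1), "inverted", ident))

    if not candidates:
        return None
    return max(candidates, key=lambda rp: (rp.length * rp.identity, rp.identity))


def classify_orientation(rp: RepeatPair) -> str:
    """"DR" when the copies match on the same strand, "IR" otherwise."""
    return "DR" if rp.orientation == "direct" else "IR"


def partition_regions(record: PlastomeRecord, rp: RepeatPair | None) -> RegionPartition:
    """Assign the two inter-repeat arcs to LSC (longer) and SSC (shorter)."""
    n = record.length
    if rp is None:
        return RegionPartition(lsc=(0, 0), ssc=(0, 0), repeat=None, genome_length=n, has_repeat=False)
    (a0, a1), (b0, b1) = rp.copy_a, rp.copy_b
    arc1 = (a1, b0)  # between copy A end and copy B start
    arc2 = (b1, a0 % n)  # wraps through the origin
    len1 = (arc1[1] - arc1[0]) % n
    len2 = (arc2[1] - arc2[0]) % n
    if len1 == 0 or len2 == 0:
        raise ValueError(f"{record.id}: repeat copies are adjacent; no single-copy arc")
    if len1 >= len2:
        lsc, ssc = arc1, arc2
    else:
        lsc, ssc = arc2, arc1
    return RegionPartition(lsc=lsc, ssc=ssc, repeat=rp, genome_length=n)


def _slice_circular(seq: str, iv: tuple[int, int]) -> str:
    s, e = iv
    if s <= e:
        return seq[s:e]
    return seq[s:] + seq[:e]


def _gc(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def region_stats(record: PlastomeRecord, partition: RegionPartition) -> RegionStats:
    """Lengths, GC content and unique gene counts per region.

    Gene counts are unique (the second repeat copy, ``copy_index > 0``,
    is excluded); GC excludes N from numerator and denominator.
    """
    seq = record.sequence
    if partition.has_repeat:
        rp = partition.repeat
        rep_seq = _slice_circular(seq, rp.copy_a) + _slice_circular(seq, rp.copy_b)
        lsc_seq = _slice_circular(seq, partition.lsc)
        ssc_seq = _slice_circular(seq, partition.ssc)
        rep_len, lsc_len, ssc_len = rp.length, partition.lsc_length, partition.ssc_length
    else:
        rep_seq, lsc_seq, ssc_seq = "", seq, ""
        rep_len, lsc_len, ssc_len = 0, len(seq), 0

    uniq = [f for f in record.features if f.copy_index == 0]
    n_protein = sum(1 for f in uniq if f.kind in ("protein", "ORF"))
    n_rrna = sum(1 for f in uniq if f.kind == "rRNA")
    n_trna = sum(1 for f in uniq if f.kind == "tRNA")
    n_introns = sum(1 for f in uniq if f.kind == "intron")
    return RegionStats(
        taxon=record.id,
        total_length=record.length,
        repeat_length=rep_len,
        lsc_length=lsc_len,
        ssc_length=ssc_len,
        gc_total=_gc(seq),
        gc_repeat=_gc(rep_seq),
        gc_lsc=_gc(lsc_seq),
        gc_ssc=_gc(ssc_seq),
        n_genes=n_protein + n_rrna + n_trna,
        n_protein=n_protein,
        n_rrna=n_rrna,
        n_trna=n_trna,
        n_introns=n_introns,
    )


def stats_table(records: list[PlastomeRecord], min_len: int = 1000):
    """Per-genome summary table (one row per record, Table-1 style)."""
    import pandas as pd

    rows = []
    for rec in records:
        rp = find_large_repeat(rec, min_len=min_len)
        part = partition_regions(rec, rp)
        rows.append(region_stats(rec, part).as_dict())
    return pd.DataFrame(rows).set_index("taxon")
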