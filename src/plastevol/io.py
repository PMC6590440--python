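"""Reading, writing and normalizing annotated plastomes and alignments.

All coordinates are 0-based, half-open, on the forward strand.  Circular
genomes are stored linearized at an arbitrary origin; features that wrap
the origin in the source file are normalized by rotating the whole
sequence (never by splitting the feature), so every feature interval
lies within ``[0, length)``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "PlastomeRecord",
    "Alignment",
    "PlastomeParseError",
    "read_plastome",
    "write_plastome",
    "rotate_record",
    "reverse_complement_record",
    "read_alignment",
    "extract_gene_order",
    "normalize_gene_name",
    "load_name_map",
]

FEATURE_KINDS = ("protein", "rRNA", "tRNA", "intron", "ORF")

IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class PlastomeParseError(ValueError):
    """Raised when an input file violates the format it claims to follow."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element of a plastome.

    ``start``/``end`` span the whole feature (introns included for a
    multi-exon gene); ``exons`` lists the coding sub-intervals in 5'->3'
    order on the feature strand.  ``copy_index`` distinguishes the
    repeat-duplicated copies of the same gene (0 for the first copy by
    genome position).  Intron features carry the host gene symbol in
    ``host_gene``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: int
    exons: tuple[tuple[int, int], ...] = ()
    copy_index: int = 0
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.name}: [{self.start}, {self.end})")
        if self.kind == "intron" and not self.host_gene:
            raise ValueError(f"intron feature {self.name} must reference a host gene")

    @property
    def exon_length(self) -> int:
        if not self.exons:
            return self.end - self.start
        return sum(e - s for s, e in self.exons)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class PlastomeRecord:
    """A circular plastome: sequence plus typed features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = {c for c in seq if c not in "ACGTN"}
        amb = bad & IUPAC_AMBIGUOUS
        if amb:
            warnings.warn(
                f"{self.id}: converting ambiguity characters {sorted(amb)} to N"
            )
            seq = "".join("N" if c in IUPAC_AMBIGUOUS else c for c in seq)
            bad -= amb
        if bad:
            raise PlastomeParseError(f"{self.id}: non-nucleotide characters {sorted(bad)}")
        self.sequence = seq
        for f in self.features:
            if not (0 <= f.start < f.end <= len(seq)):
                raise ValueError(
                    f"{self.id}: feature {f.name} [{f.start},{f.end}) outside [0,{len(seq)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes(self, kinds: tuple[str, ...] = ("protein", "rRNA", "tRNA", "ORF")) -> list[GeneFeature]:
        """Gene-level features (introns excluded) sorted by start coordinate."""
        return sorted((f for f in self.features if f.kind in kinds), key=lambda f: (f.start, f.name))

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Spliced feature sequence on the feature's strand."""
        parts = sorted(feat.exons) or [(feat.start, feat.end)]
        seq = "".join(self.sequence[s:e] for s, e in parts)
        if feat.strand == -1:
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class Alignment:
    """A gapped multiple sequence alignment."""

    taxa: list[str]
    rows: list[str]
    datatype: str  # "codon" or "nucleotide"

    def __post_init__(self) -> None:
        if self.datatype not in ("codon", "nucleotide"):
            raise ValueError("datatype must be 'codon' or 'nucleotide'")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PlastomeParseError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if self.datatype == "codon" and self.rows and len(self.rows[0]) % 3 != 0:
            raise PlastomeParseError(
                f"codon alignment length {len(self.rows[0])} not divisible by 3"
            )
        allowed = set("ACGTUN-?")
        for taxon, row in zip(self.taxa, self.rows):
            bad = {c for c in row.upper() if c not in allowed and c not in IUPAC_AMBIGUOUS}
            if bad:
                raise PlastomeParseError(f"{taxon}: non-IUPAC characters {sorted(bad)}")
        self.rows = [
            "".join("N" if c in IUPAC_AMBIGUOUS else c for c in row.upper().replace("U", "T"))
            for row in self.rows
        ]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def subset(self, taxa: list[str]) -> "Alignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        return Alignment(list(taxa), [self.rows[idx[t]] for t in taxa], self.datatype)


# ---------------------------------------------------------------------------
# gene-name normalization


def load_name_map() -> dict[str, str]:
    """Load the versioned gene-symbol normalization table shipped with the package."""
    path = Path(__file__).parent / "data" / "gene_synonyms.tsv"
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            alias, canonical = row[0], row[1]
            mapping[alias.lower()] = canonical
    return mapping


_NAME_MAP: dict[str, str] | None = None


def normalize_gene_name(name: str) -> str:
    """Map a raw annotation symbol to the canonical symbol used throughout.

    Handles case (``PsbA`` -> ``psbA``), tRNA anticodon punctuation
    (``trnT(ggu)`` -> ``trnT-GGU``) and rRNA aliases (``16S ribosomal
    RNA`` -> ``rrn16``) via the shipped mapping file, falling back to
    a couple of mechanical rewrites.
    """
    global _NAME_MAP
    if _NAME_MAP is None:
        _NAME_MAP = load_name_map()
    raw = name.strip()
    if raw.lower() in _NAME_MAP:
        return _NAME_MAP[raw.lower()]
    # mechanical rewrite for tRNA anticodon notation: trnX(abc) / trnX_abc -> trnX-ABC
    if raw.lower().startswith("trn"):
        cleaned = raw.replace("(", "-").replace(")", "").replace("_", "-")
        parts = cleaned.split("-")
        if len(parts) == 2 and len(parts[1]) == 3:
            # anticodons are written in RNA alphabet (trnT-GGU, not trnT-GGT)
            return parts[0][:3] + parts[0][3:] + "-" + parts[1].upper().replace("T", "U")
    return raw


# ---------------------------------------------------------------------------
# GenBank / FASTA reading


def _kind_of(bio_feature) -> str | None:
    t = bio_feature.type
    if t == "CDS":
        return "protein"
    if t == "rRNA":
        return "rRNA"
    if t == "tRNA":
        return "tRNA"
    if t == "intron":
        return "intron"
    if t in ("ORF", "misc_feature") and "orf" in str(bio_feature.qualifiers.get("note", "")).lower():
        return "ORF"
    return None


def _feature_name(bio_feature) -> str | None:
    for key in ("gene", "standard_name", "product", "label"):
        vals = bio_feature.qualifiers.get(key)
        if vals:
            return normalize_gene_name(vals[0])
    return None


def _wraps_origin(location, length: int) -> bool:
    parts = list(location.parts)
    if len(parts) < 2:
        return False
    # join(x..length,1..y) style wrap: a later part restarts at coordinate 0
    return any(int(parts[i + 1].start) < int(parts[i].start) for i in range(len(parts) - 1)) and any(
        int(p.end) == length for p in parts
    )


def read_plastome(path: str | Path, fmt: str = "genbank") -> PlastomeRecord:
    """Read one annotated plastome from a GenBank flat file or plain FASTA.

    GenBank compound (``join``) locations are preserved as exon lists.
    Duplicate gene names (the two repeat copies) receive distinct
    ``copy_index`` values in genome order.  A record whose annotation
    wraps the linearization origin is rotated so no feature wraps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        rec = next(SeqIO.parse(str(path), fmt))
    except StopIteration:
        raise PlastomeParseError(f"{path}: no records found")
    except ValueError as exc:
        raise PlastomeParseError(f"{path}: {exc}") from exc

    seq = str(rec.seq).upper()
    if fmt == "fasta":
        warnings.warn(f"{path}: FASTA input carries no feature table")
        return PlastomeRecord(id=rec.id, sequence=seq, features=[], source=str(path))

    # rotate away any origin-wrapping feature before converting coordinates
    shift = 0
    for bf in rec.features:
        if _kind_of(bf) and _wraps_origin(bf.location, len(seq)):
            shift = max(shift, int(max(int(p.end) for p in bf.location.parts if int(p.start) > 0) % len(seq)))
    if shift:
        rec = rec[shift:] + rec[:shift]
        seq = str(rec.seq).upper()

    features: list[GeneFeature] = []
    seen_gene_spans: set[tuple[str, int, int]] = set()
    for bf in rec.features:
        kind = _kind_of(bf)
        if kind is None:
            continue
        name = _feature_name(bf)
        if name is None:
            raise PlastomeParseError(
                f"{path}: {bf.type} feature at {bf.location} has no gene/product qualifier"
            )
        start, end = int(bf.location.start), int(bf.location.end)
        span_key = (name, start, end)
        if kind != "intron" and span_key in seen_gene_spans:
            continue  # gene + CDS/tRNA/rRNA pairs describe the same element
        seen_gene_spans.add(span_key)
        strand = 1 if (bf.location.strand or 1) >= 0 else -1
        parts = sorted(((int(p.start), int(p.end)) for p in bf.location.parts))
        if strand == -1:
            parts = parts[::-1]
        host = None
        if kind == "intron":
            host = name
            number = bf.qualifiers.get("number", ["1"])[0]
            name = f"{name}-intron{number}"
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(parts) if len(parts) > 1 else (),
                host_gene=host,
            )
        )
    if not features:
        warnings.warn(f"{path}: annotated record contains no recognized features")
    features = _assign_copy_indices(features)
    return PlastomeRecord(id=rec.id, sequence=seq, features=features, source=str(path))


def _assign_copy_indices(features: list[GeneFeature]) -> list[GeneFeature]:
    by_name: dict[tuple[str, str], int] = {}
    out = []
    for f in sorted(features, key=lambda f: (f.start, f.end, f.name)):
        key = (f.kind, f.name)
        idx = by_name.get(key, 0)
        by_name[key] = idx + 1
        out.append(replace(f, copy_index=idx))
    return out


def write_plastome(record: PlastomeRecord, path: str | Path) -> Path:
    """Write a PlastomeRecord as a GenBank flat file (round-trip safe)."""
    path = Path(path)
    kind_to_type = {"protein": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "intron": "intron", "ORF": "CDS"}
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    for f in record.features:
        parts = f.exons or ((f.start, f.end),)
        fparts = sorted(parts)
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in fparts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs if f.strand == 1 else locs[::-1])
        qualifiers = {"gene": [f.host_gene if f.kind == "intron" else f.name]}
        if f.kind == "intron":
            qualifiers["number"] = [f.name.rsplit("intron", 1)[-1]]
        rec.features.append(SeqFeature(loc, type=kind_to_type[f.kind], qualifiers=qualifiers))
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")
    return path


def write_feature_table(record: PlastomeRecord, path: str | Path) -> Path:
    """Write the feature annotation as a TSV (name, kind, start, end,
    strand, copy_index, exons)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tkind\tstart\tend\tstrand\tcopy_index\texons\n")
        for f in sorted(record.features, key=lambda f: (f.start, f.name)):
            exons = ",".join(f"{s}-{e}" for s, e in f.exons)
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t{f.copy_index}\t{exons}\n")
    return path


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate the circular genome so old coordinate ``offset`` becomes 0.

    Features that would wrap after rotation keep their extent by further
    shifting; callers choose intergenic offsets.
    """
    n = record.length
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        s = (f.start - offset) % n
        e = s + (f.end - f.start)
        if e > n:
            raise ValueError(f"rotation by {offset} splits feature {f.name}")
        shift = s - f.start
        exons = tuple((a + shift, b + shift) for a, b in f.exons)
        feats.append(replace(f, start=s, end=e, exons=exons))
    return PlastomeRecord(id=record.id, sequence=seq, features=feats, source=record.source)


def reverse_complement_record(record: PlastomeRecord) -> PlastomeRecord:
    n = record.length
    seq = str(Seq(record.sequence).reverse_complement())
    feats = []
    for f in record.features:
        s, e = n - f.end, n - f.start
        exons = tuple(sorted((n - b, n - a) for a, b in f.exons))
        if f.strand == -1:
            exons = exons[::-1]
        feats.append(replace(f, start=s, end=e, strand=-f.strand, exons=exons))
    return PlastomeRecord(id=record.id, sequence=seq, features=feats, source=record.source)


def read_alignment(path: str | Path, datatype: str = "nucleotide") -> Alignment:
    """Read a FASTA multiple alignment, validating shape and alphabet."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PlastomeParseError(f"{path}: empty alignment")
    return Alignment(
        taxa=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
        datatype=datatype,
    )


# ---------------------------------------------------------------------------
# signed gene orders


def extract_gene_order(record: PlastomeRecord, collapse_repeat: bool = False, partition=None):
    """Project a plastome onto its signed gene order.

    Genes are ordered by start coordinate around the circle with sign =
    strand.  When a :class:`~plastevol.structure.RegionPartition` is
    given, the order is rotated (and if needed reflected) to the
    canonical anchor: the first base of the LSC adjacent to repeat copy
    B, with the LSC preceding the SSC reading forward — the familiar
    LSC–IRb–SSC–IRa page layout.  Without a partition the rotation
    starts at the lexicographically smallest gene name, which is still
    rotation invariant.

    With ``collapse_repeat`` the second repeat copy's genes are dropped
    and the first copy's span is replaced by a single signed block
    (named ``__repeat__``) carrying the orientation flag.
    """
    from plastevol.rearrangement import REPEAT_BLOCK, SignedGeneOrder

    genes = record.genes()
    if not genes:
        raise ValueError(f"{record.id}: no gene features to order")
    dupes = {}
    for g in genes:
        dupes.setdefault((g.name, g.kind), []).append(g)

    blocks: list[tuple[str, int]] = [(g.name, g.strand) for g in genes]
    orientation_flag = "none"
    repeat_block = None

    if collapse_repeat:
        if partition is None:
            raise ValueError("collapse_repeat requires a RegionPartition")
        rp = partition.repeat
        orientation_flag = "IR" if rp.orientation == "inverted" else "DR"
        repeat_block = REPEAT_BLOCK

        def region_of(g):
            m = g.midpoint
            if rp.copy_a[0] <= m < rp.copy_a[1]:
                return "A"
            if rp.copy_b[0] <= m < rp.copy_b[1]:
                return "B"
            return "SC"

        blocks = []
        inserted = False
        for g in genes:
            reg = region_of(g)
            if reg == "B":
                continue
            if reg == "A":
                if not inserted:
                    # sign convention: strand of the first gene inside the
                    # lower-coordinate copy
                    blocks.append((REPEAT_BLOCK, g.strand))
                    inserted = True
                continue
            blocks.append((g.name, g.strand))
    else:
        for (name, kind), fs in dupes.items():
            if len(fs) > 1 and len({(f.start, f.end) for f in fs}) != len(fs):
                raise ValueError(f"{record.id}: overlapping duplicate features for {name}")
        blocks = [
            (g.name if g.copy_index == 0 else f"{g.name}#{g.copy_index + 1}", g.strand)
            for g in genes
        ]

    order = SignedGeneOrder(
        blocks=blocks,
        circular=True,
        repeat_block=repeat_block,
        orientation_flag=orientation_flag,
    )

    if partition is not None:
        order = _anchor_to_partition(order, genes, partition, collapse_repeat)
    else:
        order = order.canonical_rotation()
    return order


def _anchor_to_partition(order, genes, partition, collapsed):
    """Rotate/reflect so the order reads LSC, repeat, SSC, repeat(B dropped)."""
    lsc_start, lsc_end = partition.lsc
    rp = partition.repeat

    def in_lsc(mid):
        if lsc_start <= lsc_end:
            return lsc_start <= mid < lsc_end
        return mid >= lsc_start or mid < lsc_end

    names_in_lsc = [g.name for g in genes if in_lsc(g.midpoint)]
    if not names_in_lsc:
        return order.canonical_rotation()
    first_lsc = names_in_lsc[0]
    last_lsc = names_in_lsc[-1]

    base = [b for b in order.blocks]
    names = [n for n, _ in base]

    def rotated_from(name, flip):
        seq = [(n, -s) for n, s in reversed(base)] if flip else list(base)
        ns = [n for n, _ in seq]
        i = ns.index(name)
        return seq[i:] + seq[:i]

    start_name = first_lsc if first_lsc in names else None
    if start_name is None:
        return order.canonical_rotation()
    cand = rotated_from(start_name, False)
    # the repeat (or first repeat-copy gene) must come right after the LSC run
    if collapsed:
        k = len(names_in_lsc)
        ok = len(cand) > k and cand[k][0] == order.repeat_block
        if not ok:
            cand = rotated_from(last_lsc, True)
    from plastevol.rearrangement import SignedGeneOrder

    return SignedGeneOrder(
        blocks=cand,
        circular=True,
        repeat_block=order.repeat_block,
        orientation_flag=order.orientation_flag,
    )
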