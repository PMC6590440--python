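"""Synthetic plastomes, rearrangement/loss histories and sequence evolution.

Everything the analysis modules infer can be planted here with known
ground truth: circular quadripartite genomes with a two-copy repeat in
inverted (IR) or direct (DR) orientation, signed gene orders perturbed
by known inversion histories (including repeat-spanning inversions that
toggle IR<->DR), gene/intron losses placed on a tree, and codon or
nucleotide sequence evolution in which repeat-resident sites evolve at
a configurable fraction ``r`` of the single-copy rate and each
repeat-copy mutation is homogenized between the copies with probability
``gamma`` (copy-correction, modeled as instantaneous per-mutation
gene conversion with uniformly chosen direction).  All outputs are pure
functions of the configuration, including its seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from plastevol.content import load_catalog
from plastevol.io import Alignment, PlastomeRecord, GeneFeature, write_plastome
from plastevol.rearrangement import (
    REPEAT_BLOCK,
    SignedGeneOrder,
    write_orders,
)
from plastevol.rates import (
    RateClassSpec,
    codon_generator,
    codon_space,
    ds_from_t,
    f3x4_from_pi_nt,
    gtr_generator,
    parse_rate_class,
    spectral,
    transition_matrix,
)
from plastevol.structure import RegionPartition, RepeatPair
from plastevol.trees import Node, parse_newick

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedSequences",
    "simulate_history",
    "evolve_sequences",
    "make_fixture_set",
]

DEFAULT_TREE = "((A:0.10,B:0.16)AB:0.06,(C:0.09,(D:0.12,E:0.22)DE:0.05)CDE:0.04,O:0.25)Root;"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a small lycophyte-like clade: a 40-gene circular
    plastome whose rRNA operon (4 genes) sits in a large two-copy
    repeat, roughly one inversion per branch with a quarter of
    inversions spanning the repeat, a 2% per-element per-branch loss
    rate, moderate plastid-like GC, and single-copy branch lengths of
    0.05-0.3 expected substitutions per site.
    """

    n_blocks: int = 40
    repeat_genes: tuple[str, ...] = ("rrn16", "rrn23", "rrn4.5", "rrn5")
    initial_orientation: str = "IR"
    n_inversions: int = 1  # per branch (fixed count)
    p_span_repeat: float = 0.25
    loss_rate: float = 0.02
    tree: str = DEFAULT_TREE
    rate_reduction: float = 1.0  # r: repeat-region substitution-rate multiplier
    conversion_prob: float = 0.0  # gamma: per-mutation homogenization probability
    gc_bias: float = 0.36
    seed: int = 0
    # sequence-evolution conditions
    codon_sites: int = 2000  # codons per partition
    rrna_sites: int = 3000
    omega: float = 0.2
    theta: tuple[float, ...] = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
    rate_class: str = "012345"
    alpha: float = 0.5
    p_inv: float = 0.2
    # optional explicit event scripts: branch label -> list of event tuples
    branch_events: dict | None = None

    def __post_init__(self) -> None:
        for p, name in ((self.p_span_repeat, "p_span_repeat"), (self.loss_rate, "loss_rate"),
                        (self.conversion_prob, "conversion_prob"), (self.p_inv, "p_inv")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.rate_reduction <= 1.0:
            raise ValueError("rate_reduction must lie in (0, 1]")
        if self.initial_orientation not in ("IR", "DR"):
            raise ValueError("initial_orientation must be IR or DR")


# ---------------------------------------------------------------------------
# genome units


@dataclass
class _Gene:
    name: str
    sign: int
    status: str = "intact"  # intact | pseudogene


@dataclass
class _Copy:
    tag: str  # "A" | "B"
    genes: list[tuple[str, int]]
    sign: int = 1  # flip parity relative to the as-built copy


def _reverse_units(units: list) -> list:
    out = []
    for u in reversed(units):
        if isinstance(u, _Gene):
            out.append(replace(u, sign=-u.sign))
        else:
            out.append(_Copy(tag=u.tag, genes=[(n, -s) for n, s in reversed(u.genes)], sign=-u.sign))
    return out


def _orientation(units: list) -> str:
    copies = {u.tag: u for u in units if isinstance(u, _Copy)}
    a, b = copies["A"], copies["B"]
    if b.genes == a.genes:
        return "DR"
    if b.genes == [(n, -s) for n, s in reversed(a.genes)]:
        return "IR"
    raise AssertionError("repeat copies lost their mirror relationship")


def _copy_positions(units: list) -> list[int]:
    return [i for i, u in enumerate(units) if isinstance(u, _Copy)]


@dataclass
class SimulatedTruth:
    """Ground truth accompanying a simulated clade."""

    inversions: dict[str, list[dict]]  # branch label -> events
    losses: dict[str, list[tuple[str, str]]]  # branch label -> (gene, kind)
    orientation: dict[str, str]  # tip -> IR/DR
    partitions: dict[str, RegionPartition]
    tip_orders: dict[str, SignedGeneOrder]  # collapsed, repeat as one block
    root_order: SignedGeneOrder


def _collapsed_order(units: list, orientation: str) -> SignedGeneOrder:
    """One repeat block at the first-encountered copy, signed by the strand
    of that copy's first internal gene (matches what extraction from an
    annotated record yields)."""
    blocks: list[tuple[str, int]] = []
    seen_copy = False
    for u in units:
        if isinstance(u, _Copy):
            if not seen_copy:
                blocks.append((REPEAT_BLOCK, u.genes[0][1]))
                seen_copy = True
        else:
            blocks.append((u.name, u.sign))
    return SignedGeneOrder(
        blocks=blocks, circular=True, repeat_block=REPEAT_BLOCK, orientation_flag=orientation
    )


def _choose_interval(units: list, rng: np.random.Generator, span_repeat: bool, max_tries: int = 200):
    n = len(units)
    for _ in range(max_tries):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        if i > j:
            i, j = j, i
        if j - i + 1 >= n:
            continue
        inside = sum(1 for u in units[i : j + 1] if isinstance(u, _Copy))
        if span_repeat and inside == 1:
            return i, j
        if not span_repeat and inside == 0 and j >= i:
            return i, j
    raise RuntimeError("could not sample a suitable inversion interval")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def _coding_seq(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random sense codons (no internal stops) + TAA."""
    space = codon_space()
    pi_nt = np.tile([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], (3, 1))
    _, pi = f3x4_from_pi_nt(pi_nt)
    idx = rng.choice(space.n, size=max(0, n_codons - 2), p=pi)
    return "ATG" + "".join(space.codons[i] for i in idx) + "TAA"


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def simulate_history(config: SimulationConfig) -> tuple[dict[str, PlastomeRecord], SimulatedTruth]:
    """Evolve a quadripartite root genome along a tree by inversions and losses.

    The root genome carries the repeat genes in two copies flanking the
    small single-copy region, in the configured orientation.  Inversions
    never split a repeat copy; an inversion containing exactly one copy
    spans the repeat and toggles IR<->DR.  Losses hit single-copy genes
    (removal or pseudogenization with equal probability).  Tip genomes
    are emitted as fully annotated records with planted partitions.
    """
    rng = np.random.default_rng(config.seed)
    catalog = load_catalog()
    tree = parse_newick(config.tree) if isinstance(config.tree, str) else config.tree

    n_sc = config.n_blocks - len(config.repeat_genes)
    if n_sc < 4:
        raise ValueError("n_blocks too small for the requested repeat")
    trna_picks = [e for e in ("trnT-GGU", "trnD-GUC", "trnF-GAA", "trnQ-UUG", "trnH-GUG", "trnY-GUA")
                  if e not in config.repeat_genes][: max(0, n_sc - 4)][:6]
    protein_pool = [e for e in catalog.index
                    if catalog.loc[e, "category"] == "protein" and e not in config.repeat_genes]
    sc_genes = protein_pool[: n_sc - len(trna_picks)] + trna_picks
    n_lsc = int(round(n_sc * 0.75))

    rep = [(g, 1) for g in config.repeat_genes]
    copy_a = _Copy("A", [(n, s) for n, s in rep])
    if config.initial_orientation == "IR":
        copy_b = _Copy("B", [(n, -s) for n, s in reversed(rep)])
    else:
        copy_b = _Copy("B", [(n, s) for n, s in rep])
    signs = rng.choice([1, -1], size=n_sc)
    root_units: list = (
        [_Gene(g, int(s)) for g, s in zip(sc_genes[:n_lsc], signs[:n_lsc])]
        + [copy_a]
        + [_Gene(g, int(s)) for g, s in zip(sc_genes[n_lsc:], signs[n_lsc:])]
        + [copy_b]
    )
    root_orientation = config.initial_orientation

    inv_truth: dict[str, list[dict]] = {}
    loss_truth: dict[str, list[tuple[str, str]]] = {}
    states: dict[int, tuple[list, str]] = {id(tree): (root_units, root_orientation)}

    for node in tree.preorder():
        if node.parent is None:
            continue
        units, orient = states[id(node.parent)]
        units = [replace(u) if isinstance(u, _Gene) else _Copy(u.tag, list(u.genes)) for u in units]
        events: list[dict] = []
        script = (config.branch_events or {}).get(node.label)
        if script is not None:
            for ev in script:
                units, orient, rec = _apply_scripted(units, orient, ev)
                if rec is not None:
                    events.append(rec)
        else:
            for _ in range(config.n_inversions):
                span = bool(rng.random() < config.p_span_repeat)
                i, j = _choose_interval(units, rng, span)
                seg_names = [u.name if isinstance(u, _Gene) else f"repeat:{u.tag}" for u in units[i : j + 1]]
                units[i : j + 1] = _reverse_units(units[i : j + 1])
                if span:
                    orient = "DR" if orient == "IR" else "IR"
                events.append({"interval": (i, j), "spans_repeat": span, "content": seg_names})
        # losses on single-copy genes
        losses: list[tuple[str, str]] = []
        if config.loss_rate > 0 and script is None:
            keep: list = []
            for u in units:
                if isinstance(u, _Gene) and u.status == "intact" and rng.random() < config.loss_rate:
                    if rng.random() < 0.5:
                        losses.append((u.name, "loss"))
                        continue
                    losses.append((u.name, "pseudogenization"))
                    u = replace(u, status="pseudogene")
                keep.append(u)
            units = keep
        inv_truth[node.label] = events
        loss_truth[node.label] = losses
        states[id(node)] = (units, orient)

    # instantiate tips
    gene_lengths: dict[str, int] = {}
    gene_seqs: dict[str, str] = {}
    rrna_len = {"rrn16": 1491, "rrn23": 2811, "rrn4.5": 102, "rrn5": 120}
    for g in sc_genes + list(config.repeat_genes):
        cat = catalog.loc[g, "category"] if g in catalog.index else "protein"
        if cat == "tRNA":
            gene_seqs[g] = _random_seq(rng, 72, config.gc_bias + 0.1)
        elif cat == "rRNA":
            gene_seqs[g] = _random_seq(rng, rrna_len.get(g, 1500), config.gc_bias + 0.15)
        else:
            ncod = int(rng.integers(100, 480))
            gene_seqs[g] = _coding_seq(rng, ncod, config.gc_bias)
        gene_lengths[g] = len(gene_seqs[g])

    spacer_of: dict[str, str] = {}

    def spacer(key: str) -> str:
        if key not in spacer_of:
            digest = zlib.crc32(key.encode()) % (2**31)
            spacer_of[key] = _random_seq(
                np.random.default_rng((config.seed, digest)), 120, config.gc_bias - 0.05
            )
        return spacer_of[key]

    records: dict[str, PlastomeRecord] = {}
    partitions: dict[str, RegionPartition] = {}
    orientations: dict[str, str] = {}
    tip_orders: dict[str, SignedGeneOrder] = {}

    for leaf in tree.leaves():
        units, orient = states[id(leaf)]
        seq_parts: list[str] = []
        feats: list[GeneFeature] = []
        pos = 0
        copy_spans: dict[str, tuple[int, int]] = {}
        primary_seq: str | None = None
        primary_feats: list[GeneFeature] = []

        def emit_gene(g: _Gene, pos: int) -> tuple[str, list[GeneFeature], int]:
            s = gene_seqs[g.name]
            if g.status == "pseudogene":
                mid = len(s) // 2
                s = s[:mid] + s[mid + 1 :]  # 1-bp deletion: frameshift
            if g.sign == -1:
                s = _revcomp(s)
            cat = catalog.loc[g.name, "category"] if g.name in catalog.index else "protein"
            kind = {"protein": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}.get(cat, "protein")
            f = GeneFeature(name=g.name, kind=kind, start=pos, end=pos + len(s), strand=g.sign)
            return s, [f], pos + len(s)

        for u in units:
            if isinstance(u, _Gene):
                sp = spacer(f"sc:{u.name}")
                seq_parts.append(sp)
                pos += len(sp)
                s, fs, pos = emit_gene(u, pos)
                seq_parts.append(s)
                feats.extend(fs)
            else:
                sp = spacer(f"copyflank:{u.tag}")
                seq_parts.append(sp)
                pos += len(sp)
                start = pos
                if primary_seq is None:
                    inner_parts = []
                    inner_feats = []
                    ip = 0
                    for gname, gsign in u.genes:
                        isp = spacer(f"rep:{gname}")
                        inner_parts.append(isp)
                        ip += len(isp)
                        s = gene_seqs[gname]
                        if gsign == -1:
                            s = _revcomp(s)
                        cat = catalog.loc[gname, "category"] if gname in catalog.index else "rRNA"
                        kind = {"protein": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}.get(cat, "rRNA")
                        inner_feats.append(GeneFeature(name=gname, kind=kind, start=ip, end=ip + len(s), strand=gsign))
                        inner_parts.append(s)
                        ip += len(s)
                    region = "".join(inner_parts)
                    primary_seq, primary_feats = region, inner_feats
                else:
                    # the second copy is an exact sequence copy of the first
                    # (same strand for DR, reverse complement for IR)
                    if orient == "DR":
                        region = primary_seq
                        inner_feats = [replace(f) for f in primary_feats]
                    else:
                        region = _revcomp(primary_seq)
                        L = len(region)
                        inner_feats = [
                            replace(f, start=L - f.end, end=L - f.start, strand=-f.strand)
                            for f in primary_feats
                        ]
                for f in inner_feats:
                    feats.append(replace(f, start=f.start + start, end=f.end + start))
                seq_parts.append(region)
                pos += len(region)
                copy_spans[u.tag] = (start, pos)
        tail = spacer("tail")
        seq_parts.append(tail)
        pos += len(tail)
        sequence = "".join(seq_parts)

        from plastevol.io import _assign_copy_indices

        rec = PlastomeRecord(
            id=leaf.label,
            sequence=sequence,
            features=_assign_copy_indices(feats),
            source="simulated",
        )
        a, b = copy_spans["A"], copy_spans["B"]
        if a[0] > b[0]:
            a, b = b, a
        rp = RepeatPair(copy_a=a, copy_b=b,
                        orientation="direct" if orient == "DR" else "inverted", identity=1.0)
        arc1 = (a[1], b[0])
        arc2 = (b[1], a[0])
        n = len(sequence)
        len1 = (arc1[1] - arc1[0]) % n
        len2 = (arc2[1] - arc2[0]) % n
        lsc, ssc = (arc1, arc2) if len1 >= len2 else (arc2, arc1)
        partitions[leaf.label] = RegionPartition(lsc=lsc, ssc=ssc, repeat=rp, genome_length=n)
        orientations[leaf.label] = orient
        records[leaf.label] = rec
        tip_orders[leaf.label] = _collapsed_order(units, orient)

    truth = SimulatedTruth(
        inversions=inv_truth,
        losses=loss_truth,
        orientation=orientations,
        partitions=partitions,
        tip_orders=tip_orders,
        root_order=_collapsed_order(root_units, root_orientation),
    )
    return records, truth


def _apply_scripted(units: list, orient: str, ev: tuple):
    kind = ev[0]
    if kind == "invert":
        _, i, j = ev
        inside = sum(1 for u in units[i : j + 1] if isinstance(u, _Copy))
        if inside == 2:
            raise ValueError("scripted inversion may not contain both repeat copies")
        span = inside == 1
        seg = [u.name if isinstance(u, _Gene) else f"repeat:{u.tag}" for u in units[i : j + 1]]
        units[i : j + 1] = _reverse_units(units[i : j + 1])
        if span:
            orient = "DR" if orient == "IR" else "IR"
        return units, orient, {"interval": (i, j), "spans_repeat": span, "content": seg}
    if kind == "lose":
        _, gene = ev
        units = [u for u in units if not (isinstance(u, _Gene) and u.name == gene)]
        return units, orient, None
    if kind == "pseudo":
        _, gene = ev
        units = [replace(u, status="pseudogene") if isinstance(u, _Gene) and u.name == gene else u for u in units]
        return units, orient, None
    raise ValueError(f"unknown scripted event {kind!r}")


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass
class SimulatedSequences:
    """Alignments plus generating truth for the rate-estimation modules."""

    sc_codon: Alignment
    repeat_codon: Alignment  # copy A of the duplicated partition
    repeat_codon_b: Alignment
    rrna_nt: Alignment
    true_ds_sc: dict[str, float]
    true_ds_repeat: dict[str, float]
    true_d_rrna: dict[str, float]
    true_t: dict[str, float]


def _pi_nt(config: SimulationConfig) -> np.ndarray:
    gc = config.gc_bias
    return np.tile([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], (3, 1))


def _evolve_codon_matrix(seqs, P, rng):
    out = np.empty_like(seqs)
    for s in np.unique(seqs):
        mask = seqs == s
        out[mask] = rng.choice(P.shape[1], size=int(mask.sum()), p=P[s])
    return out


def evolve_sequences(tree: str | Node, config: SimulationConfig) -> SimulatedSequences:
    """Simulate codon and nucleotide alignments along a tree.

    Branch lengths are expected substitutions per (codon or nucleotide)
    site in the single-copy partition.  Repeat-partition sites evolve at
    ``rate_reduction * t`` and each mutation there is homogenized
    between the two copies with probability ``conversion_prob``
    (uniformly chosen direction), so the copies stay correlated without
    changing the marginal substitution rate; the orientation of the
    copies plays no role.  True per-branch synonymous divergences are
    recorded from the generating parameters.
    """
    rng = np.random.default_rng(config.seed + 1)
    root = parse_newick(tree) if isinstance(tree, str) else tree
    spec = parse_rate_class(config.rate_class)
    theta6 = np.asarray(config.theta, dtype=float)
    # honour the configured tying pattern (tied classes take the last value)
    theta_dense = np.zeros(spec.free_count)
    for pair_idx, cls in enumerate(spec.assignment):
        theta_dense[cls] = config.theta[pair_idx]
    pi_nt = _pi_nt(config)
    _, pi = f3x4_from_pi_nt(pi_nt)
    Q, total, _ = codon_generator(theta_dense, config.omega, pi_nt, spec)
    Qn = Q / total
    lam, U, V = spectral(Qn, pi)
    space = codon_space()
    exit_rate = -np.diag(Qn)
    jump = Qn.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / np.maximum(exit_rate[:, None], 1e-300)

    ncod = config.codon_sites
    root_sc = rng.choice(space.n, size=ncod, p=pi)
    root_rep = rng.choice(space.n, size=ncod, p=pi)

    sc_states: dict[int, np.ndarray] = {id(root): root_sc}
    rep_states: dict[int, tuple[np.ndarray, np.ndarray]] = {id(root): (root_rep, root_rep.copy())}
    true_t: dict[str, float] = {}
    r = config.rate_reduction
    gamma = config.conversion_prob

    for node in root.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        true_t[node.label] = t
        P = transition_matrix(lam, U, V, t)
        sc_states[id(node)] = _evolve_codon_matrix(sc_states[id(node.parent)], P, rng)
        a, b = rep_states[id(node.parent)]
        if gamma <= 0.0:
            Pr = transition_matrix(lam, U, V, r * t)
            na = _evolve_codon_matrix(a, Pr, rng)
            nb = _evolve_codon_matrix(b, Pr, rng)
        else:
            na, nb = _gillespie_pair(a, b, r * t, exit_rate, jump, gamma, rng)
        rep_states[id(node)] = (na, nb)

    def codon_aln(states: dict[int, np.ndarray], which=None) -> Alignment:
        taxa, rows = [], []
        for leaf in root.leaves():
            st = states[id(leaf)]
            if which is not None:
                st = st[which]
            taxa.append(leaf.label)
            rows.append("".join(space.codons[s] for s in st))
        return Alignment(taxa, rows, "codon")

    sc_aln = codon_aln(sc_states)
    rep_a = codon_aln(rep_states, which=0)
    rep_b = codon_aln(rep_states, which=1)

    # rRNA-style nucleotide partition under GTR+G+I
    pig = _nt_pi(config)
    Qg = gtr_generator(theta6, pig, parse_rate_class("012345"))
    lamg, Ug, Vg = spectral(Qg, pig)
    nsites = config.rrna_sites
    from scipy import stats as _stats

    k = 4
    cat_rates = _stats.gamma.ppf((2 * np.arange(k) + 1) / (2 * k), a=config.alpha, scale=1.0 / config.alpha)
    cat_rates = cat_rates / cat_rates.mean()
    site_rates = np.where(
        rng.random(nsites) < config.p_inv, 0.0, cat_rates[rng.integers(0, k, size=nsites)]
    )
    root_nt = rng.choice(4, size=nsites, p=pig)
    nt_states: dict[int, np.ndarray] = {id(root): root_nt}
    for node in root.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        child = nt_states[id(node.parent)].copy()
        for rate in np.unique(site_rates):
            mask = site_rates == rate
            if rate == 0.0:
                continue
            P = transition_matrix(lamg, Ug, Vg, rate * t)
            child[mask] = _evolve_codon_matrix(nt_states[id(node.parent)][mask], P, rng)
        nt_states[id(node)] = child
    taxa, rows = [], []
    for leaf in root.leaves():
        taxa.append(leaf.label)
        rows.append("".join("ACGT"[s] for s in nt_states[id(leaf)]))
    rrna = Alignment(taxa, rows, "nucleotide")

    ds_unit = ds_from_t(1.0, theta_dense, config.omega, pi_nt, spec)
    true_ds_sc = {b: t * ds_unit for b, t in true_t.items()}
    true_ds_rep = {b: r * t * ds_unit for b, t in true_t.items()}
    # expected substitutions per site: invariant sites never change, the
    # gamma categories have mean one among variable sites
    true_d = {b: t * (1.0 - config.p_inv) for b, t in true_t.items()}
    return SimulatedSequences(
        sc_codon=sc_aln,
        repeat_codon=rep_a,
        repeat_codon_b=rep_b,
        rrna_nt=rrna,
        true_ds_sc=true_ds_sc,
        true_ds_repeat=true_ds_rep,
        true_d_rrna=true_d,
        true_t=true_t,
    )


def _nt_pi(config: SimulationConfig) -> np.ndarray:
    gc = config.gc_bias
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _gillespie_pair(a, b, t, exit_rate, jump, gamma, rng):
    """Joint evolution of the two repeat copies with copy-correction."""
    na, nb = a.copy(), b.copy()
    n_states = jump.shape[0]
    for site in range(len(na)):
        sa, sb = int(na[site]), int(nb[site])
        clock = 0.0
        while True:
            ra, rb = exit_rate[sa], exit_rate[sb]
            tot = ra + rb
            if tot <= 0:
                break
            clock += rng.exponential(1.0 / tot)
            if clock >= t:
                break
            on_a = rng.random() < ra / tot
            src = sa if on_a else sb
            new = int(rng.choice(n_states, p=jump[src]))
            if rng.random() < gamma:
                if rng.random() < 0.5:
                    sa = sb = new  # conversion spreads the mutation
                # else conversion erases it: no change
            else:
                if on_a:
                    sa = new
                else:
                    sb = new
        na[site], nb[site] = sa, sb
    return na, nb


# ---------------------------------------------------------------------------
# fixture set


FIXTURE_TREE_14 = (
    "((((Hluc1,Hluc2)Huperzia,Hser)Huperzioideae,((Dobs,Ddig)DobsDdig,Lcla)Lycopodioideae)Lycopodiaceae,"
    "(((Ifla,Ipie)IflaIpie,Imal)Isoetes,"
    "(Skra,(Slep,(Smoe,(Stam,Sunc)StamSunc)SmoeStamSunc)SlepSmoeStamSunc)Selaginella)IsoSel)Root;"
)

MINI_CLADE_TREE = (
    "(((T1:0.05,T2:0.05)T12:0.05,T3:0.08)Static:0.05,"
    "(T4:0.1,(T5:0.1,(T6:0.08,T7:0.08)T67:0.04)T567:0.04)Dynamic:0.05)Root;"
)

# Collapsed ancestral gene order used for the published-style encodings:
# LSC genes, the repeat block, then SSC genes (inverted orientation).
_ANCESTRAL_BLOCKS: list[tuple[str, int]] = [
    ("psbA", 1), ("matK", -1), ("trnQ-UUG", 1), ("psbK", 1), ("atpA", 1),
    ("atpB", 1), ("rbcL", 1), ("petA", 1), ("psbB", 1), ("rpoA", -1),
    ("rps11", -1), ("rps8", -1), ("rps4", 1), ("trnF-GAA", 1), ("ycf2", 1),
    (REPEAT_BLOCK, 1),
    ("ndhF", -1), ("rpl32", 1), ("ccsA", 1), ("ndhD", -1), ("ndhA", -1),
    ("ycf1", 1), ("chlN", -1), ("chlL", -1),
]


def _published_orders() -> dict[str, SignedGeneOrder]:
    """Hand-encoded gene orders for the published comparisons.

    Each derived order is produced by replaying the inferred inversion
    series on the ancestral order, so the encodings are internally
    consistent: one repeat-spanning inversion for the direct-repeat
    Selaginella genomes, two overlapping inversions for the Isoetes
    ycf2 relocation, five inversions plus a tandem duplication for the
    most rearranged genome.
    """
    from plastevol.rearrangement import apply_reversal

    def order(blocks, n_span):
        flag = "IR" if n_span % 2 == 0 else "DR"
        return SignedGeneOrder(list(blocks), circular=True, repeat_block=REPEAT_BLOCK, orientation_flag=flag)

    anc = list(_ANCESTRAL_BLOCKS)

    def idx_of(blocks, name):
        return [n for n, _ in blocks].index(name)

    out: dict[str, SignedGeneOrder] = {}
    out["Ancestral"] = order(anc, 0)
    out["Lycopodiaceae"] = order(anc, 0)

    # S1: one endpoint between rps4 and trnF-GAA, the other just past the
    # repeat/SSC boundary; spans the repeat -> IR becomes DR.
    s1 = apply_reversal(anc, idx_of(anc, "trnF-GAA"), idx_of(anc, "ndhF"))
    out["Skra"] = order(s1, 1)

    # Slep: S1 then a second repeat-spanning inversion (back to IR)
    s2 = apply_reversal(s1, idx_of(s1, "ndhF"), idx_of(s1, "ycf2"))
    out["Slep"] = order(s2, 2)

    # Smoe: S1 then a different repeat-spanning inversion (back to IR)
    s3 = apply_reversal(s1, idx_of(s1, REPEAT_BLOCK), idx_of(s1, "rpl32"))
    out["Smoe"] = order(s3, 2)

    # Stam: S1 then an inversion confined to single-copy sequence (stays DR)
    s4 = apply_reversal(s1, idx_of(s1, "ccsA"), idx_of(s1, "ndhA"))
    out["Stam"] = order(s4, 1)

    # Sunc: S1, then three more repeat-spanning inversions and one
    # single-copy inversion, plus a tandem duplication of trnQ-UUG+psbK.
    s5 = apply_reversal(s1, idx_of(s1, REPEAT_BLOCK), idx_of(s1, "rpl32"))
    s6 = apply_reversal(s5, idx_of(s5, "atpB"), idx_of(s5, "petA"))
    s7 = apply_reversal(s6, idx_of(s6, "ycf2"), idx_of(s6, REPEAT_BLOCK))
    s8 = apply_reversal(s7, idx_of(s7, REPEAT_BLOCK), idx_of(s7, "ccsA"))
    sunc = list(s8)
    qi = idx_of(sunc, "trnQ-UUG")
    ki = idx_of(sunc, "psbK")
    lo = min(qi, ki)
    dup = sunc[lo : lo + 2]
    sunc = sunc[: lo + 2] + dup + sunc[lo + 2 :]
    flag = "IR"  # four repeat-spanning events from IR
    out["Sunc"] = SignedGeneOrder(sunc, circular=True, repeat_block=REPEAT_BLOCK, orientation_flag=flag)

    # Isoetes: two overlapping repeat-spanning inversions relocate ycf2
    i1 = apply_reversal(anc, idx_of(anc, "ycf2"), idx_of(anc, "ndhF"))
    i2 = apply_reversal(i1, idx_of(i1, "ndhF"), idx_of(i1, REPEAT_BLOCK))
    out["Isoetes"] = order(i2, 2)
    return out


# hand-encoded functional-content differences relative to the full catalog
_SEL_SHARED_PROTEIN_LOSSES = [
    "rps15", "rps16", "rpl22", "rpl32", "rpl33", "ycf94", "ycf66", "cemA", "ycf12",
]
_STAM_SLEP_NDH = ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK"]
_TRNA_RETAINED = {
    "Stam": ["trnE-UUC", "trnfM-CAU", "trnI-CAU", "trnM-CAU", "trnN-GUU", "trnQ-UUG"],
    "Skra": ["trnE-UUC", "trnfM-CAU", "trnI-CAU", "trnM-CAU", "trnN-GUU", "trnQ-UUG",
             "trnD-GUC", "trnH-GUG", "trnW-CCA", "trnY-GUA"],
    "Slep": ["trnE-UUC", "trnfM-CAU", "trnI-CAU", "trnM-CAU", "trnN-GUU", "trnQ-UUG",
             "trnD-GUC", "trnH-GUG", "trnW-CCA", "trnY-GUA", "trnP-UGG", "trnR-ACG"],
    "Sunc": ["trnE-UUC", "trnfM-CAU", "trnI-CAU", "trnM-CAU", "trnN-GUU", "trnQ-UUG",
             "trnD-GUC", "trnH-GUG", "trnW-CCA", "trnY-GUA", "trnP-UGG", "trnR-ACG"],
    "Smoe": ["trnE-UUC", "trnfM-CAU", "trnI-CAU", "trnM-CAU", "trnN-GUU", "trnQ-UUG",
             "trnD-GUC", "trnH-GUG", "trnW-CCA", "trnY-GUA", "trnP-UGG", "trnR-ACG", "trnC-GCA"],
}
_INTRONS_RETAINED = {
    "Smoe": ["atpF-intron1", "ndhA-intron1", "ndhB-intron1", "petB-intron1", "petD-intron1",
             "rpl2-intron1", "rpl16-intron1", "rpoC1-intron1", "rps12-intron1", "rps12-intron2",
             "ycf3-intron2"],
    "Sunc": ["atpF-intron1", "ndhA-intron1", "ndhB-intron1", "petB-intron1", "petD-intron1",
             "rpl2-intron1", "rpl16-intron1", "rpoC1-intron1", "rps12-intron1", "rps12-intron2",
             "ycf3-intron2"],
    "Skra": ["atpF-intron1", "ndhA-intron1", "ndhB-intron1", "petB-intron1", "petD-intron1",
             "rpl2-intron1", "rpl16-intron1", "rps12-intron1", "rps12-intron2"],
    "Stam": ["atpF-intron1", "petB-intron1", "petD-intron1", "rpl2-intron1",
             "rps12-intron1", "rps12-intron2", "ycf3-intron2"],
    "Slep": ["atpF-intron1", "petB-intron1", "petD-intron1", "rpl2-intron1", "rpl16-intron1",
             "rps12-intron1", "rps12-intron2"],
}


def content_matrix_states() -> "pd.DataFrame":
    """The hand-encoded published functional-content matrix (14 plastomes)."""
    import pandas as pd

    catalog = load_catalog()
    taxa = ["Dobs", "Ddig", "Lcla", "Hluc1", "Hluc2", "Hser",
            "Ifla", "Imal", "Ipie", "Skra", "Slep", "Smoe", "Stam", "Sunc"]
    lyc = taxa[:6]
    iso = taxa[6:9]
    data: dict[str, dict[str, str]] = {}
    for taxon in taxa:
        col: dict[str, str] = {}
        for el in catalog.index:
            cat = catalog.loc[el, "category"]
            col[el] = "present" if cat == "intron" else "intact"
        if taxon in lyc:
            col["trnT-GGU"] = "absent"
        elif taxon in iso:
            for g in ("accD", "infA", "rps2", "rps16"):
                col[g] = "pseudogene"
            col["ycf94"] = "absent"
            col["rps16-intron1"] = "absent"
        else:
            for g in _SEL_SHARED_PROTEIN_LOSSES:
                col[g] = "absent"
            col["rps18"] = "absent"
            extra: list[str] = []
            if taxon == "Skra":
                extra = ["matK", "rps2", "rps8", "rps11", "rps14", "rpl20"]
            elif taxon == "Slep":
                extra = ["matK", "accD"] + _STAM_SLEP_NDH
            elif taxon == "Smoe":
                col["infA"] = "pseudogene"
            elif taxon == "Stam":
                extra = ["rps2", "rps8", "rps11", "rps14", "rpl14", "rpl20", "accD", "infA"] + _STAM_SLEP_NDH
            for g in extra:
                col[g] = "absent"
            retained_trna = set(_TRNA_RETAINED[taxon])
            for el in catalog.index:
                if catalog.loc[el, "category"] == "tRNA" and el not in retained_trna:
                    col[el] = "absent"
            retained_introns = set(_INTRONS_RETAINED[taxon])
            for el in catalog.index:
                if catalog.loc[el, "category"] == "intron":
                    col[el] = "present" if el in retained_introns else "absent"
        data[taxon] = col
    df = pd.DataFrame(data).T[list(catalog.index)]
    # the split of ycf2 into two reading frames, a derived character of the
    # Lycopodioideae, is scored separately from gene loss
    df["ycf2_split"] = ["present" if t in ("Dobs", "Ddig", "Lcla") else "absent" for t in df.index]
    return df


def make_fixture_set(seed: int, outdir: str | Path) -> Path:
    """Write the deterministic fixture directory.

    Contents: a simulated 7-taxon mini-clade (GenBank records + truth)
    exercising an IR->DR->IR trajectory, a two-inversion gene relocation
    and a static lineage; the hand-encoded published content matrix and
    gene orders; and the fixed species topology.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # mini-clade with scripted history (deterministic given seed)
    config = SimulationConfig(
        seed=seed,
        tree=MINI_CLADE_TREE,
        n_inversions=0,
        loss_rate=0.0,
        branch_events={
            # stem of the dynamic clade: repeat-spanning inversion (IR -> DR)
            "Dynamic": [("invert", 26, 31)],
            # T5: a second overlapping spanning inversion relocates a gene
            # (DR -> IR), the two-step relocation pattern
            "T5": [("invert", 26, 30)],
            # T6 stem reverts to IR with different endpoints
            "T67": [("invert", 25, 31)],
            # T7 additionally inverts within single-copy sequence
            "T7": [("invert", 2, 5)],
            # a loss on the static side exercises the content module
            "Static": [("lose", "trnT-GGU")],
        },
    )
    records, truth = simulate_history(config)
    gb_dir = outdir / "mini_clade"
    gb_dir.mkdir(exist_ok=True)
    for tip, rec in sorted(records.items()):
        write_plastome(rec, gb_dir / f"{tip}.gb")
    with open(gb_dir / "tree.nwk", "w") as fh:
        fh.write(MINI_CLADE_TREE + "\n")
    truth_payload = {
        "orientation": truth.orientation,
        "inversions": {k: [{**e, "interval": list(e["interval"])} for e in v] for k, v in truth.inversions.items()},
        "losses": truth.losses,
    }
    with open(gb_dir / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    write_orders(truth.tip_orders, gb_dir / "tip_orders.txt")

    # published encodings
    write_orders(_published_orders(), outdir / "published_orders.txt")
    content_matrix_states().to_csv(outdir / "content_matrix.tsv", sep="\t")
    with open(outdir / "lycophyte_tree.nwk", "w") as fh:
        fh.write(FIXTURE_TREE_14 + "\n")
    return outdir
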