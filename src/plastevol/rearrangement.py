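"""Signed gene orders, reversal distances and inversion scenarios.

Genomes are compared as circular signed permutations of gene/block
identifiers.  Distances and explicit scenarios are computed after
linearizing both orders at a shared canonical anchor, so a reversal acts
on a contiguous index interval of the linear order.  The exact engine is
iterative-deepening A* over reversals, guided by the breakpoint-graph
cycle bound ``d >= (n + 1) - c`` (each reversal changes the number of
cycles by at most one), which is admissible and consistent; an
exhaustive breadth-first oracle in the test-suite cross-checks it.

The large two-copy repeat is carried as a single signed block.  An
inversion whose interval contains that block exchanges sequence between
the two single-copy regions and flips the relative orientation of the
repeat copies: inverted <-> direct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "REPEAT_BLOCK",
    "SignedGeneOrder",
    "InversionEvent",
    "DuplicationEvent",
    "ScenarioResult",
    "collapse_to_blocks",
    "breakpoint_count",
    "reversal_distance",
    "infer_inversion_scenario",
    "place_events_on_tree",
    "apply_reversal",
    "write_orders",
    "read_orders",
]

REPEAT_BLOCK = "__repeat__"


@dataclass
class SignedGeneOrder:
    """An ordered list of signed blocks representing one (circular) genome."""

    blocks: list[tuple[str, int]]
    circular: bool = True
    repeat_block: str | None = None
    orientation_flag: str = "none"  # "IR" | "DR" | "none"
    members: dict[str, list[tuple[str, int]]] | None = None

    def __post_init__(self) -> None:
        # duplicates are tolerated here (pre-collapse orders may carry tandem
        # duplications); distance operations require a duplicate-free alphabet
        for _, s in self.blocks:
            if s not in (1, -1):
                raise ValueError("block signs must be +1/-1")

    def _require_unique(self) -> None:
        names = [n for n, _ in self.blocks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"duplicate block identifiers {dupes}; resolve with collapse_to_blocks"
            )

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.blocks]

    def reversed_order(self) -> "SignedGeneOrder":
        """The same genome read from the other strand."""
        return replace(self, blocks=[(n, -s) for n, s in reversed(self.blocks)])

    def rotated(self, i: int) -> "SignedGeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        return replace(self, blocks=self.blocks[i:] + self.blocks[:i])

    def canonical_rotation(self) -> "SignedGeneOrder":
        """Rotate so the lexicographically smallest block name comes first."""
        if not self.circular or not self.blocks:
            return self
        i = min(range(len(self.blocks)), key=lambda i: self.blocks[i][0])
        return self.rotated(i)

    def anchored_to(self, other: "SignedGeneOrder") -> "SignedGeneOrder":
        """Rotate (and reflect if needed) so this order starts with the same
        signed block as ``other``; used to linearize circular orders for
        distance computation."""
        if not self.circular:
            return self
        anchor, sign = other.blocks[0]
        cand = self if anchor in self.names else None
        if cand is None:
            raise ValueError(f"anchor block {anchor!r} missing")
        i = self.names.index(anchor)
        out = self.rotated(i)
        if out.blocks[0][1] != sign:
            out = out.reversed_order()
            out = out.rotated(out.names.index(anchor))
        return out

    def adjacency_set(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        """Signed adjacencies, normalized for strand so that an adjacency and
        its reverse-complement reading are the same object."""
        self._require_unique()
        pairs = list(zip(self.blocks, self.blocks[1:]))
        if self.circular and len(self.blocks) > 1:
            pairs.append((self.blocks[-1], self.blocks[0]))
        out = set()
        for (a, sa), (b, sb) in pairs:
            fwd = ((a, sa), (b, sb))
            rev = ((b, -sb), (a, -sa))
            out.add(min(fwd, rev))
        return out


@dataclass(frozen=True)
class InversionEvent:
    """One inversion: an inclusive index interval of the current order."""

    interval: tuple[int, int]
    spans_repeat: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        i, j = self.interval
        if j < i:
            raise ValueError("empty inversion interval")


@dataclass(frozen=True)
class DuplicationEvent:
    block: str
    placement: str = "tandem"


@dataclass
class ScenarioResult:
    """A minimum-length inversion scenario between two gene orders."""

    events: list[InversionEvent]
    distance: int
    breakpoints_initial: int
    orientation_trajectory: list[str]
    optimal: bool = True
    co_optima: list[list[InversionEvent]] = field(default_factory=list)
    duplications: list[DuplicationEvent] = field(default_factory=list)
    lower_bound: int | None = None

    @property
    def n_co_optimal(self) -> int:
        return len(self.co_optima)


def apply_reversal(blocks: list[tuple[str, int]], i: int, j: int) -> list[tuple[str, int]]:
    """Reverse blocks[i..j] inclusive, flipping signs."""
    mid = [(n, -s) for n, s in reversed(blocks[i : j + 1])]
    return blocks[:i] + mid + blocks[j + 1 :]


# ---------------------------------------------------------------------------
# block collapse


def collapse_to_blocks(
    source: SignedGeneOrder, target: SignedGeneOrder
) -> tuple[SignedGeneOrder, SignedGeneOrder, list[DuplicationEvent]]:
    """Reduce two gene orders to a common alphabet of maximal synteny blocks.

    Elements private to one genome are dropped (gene losses are the
    content module's business).  A block occurring twice in the target
    and once in the source is accepted only as a tandem duplication and
    recorded as a :class:`DuplicationEvent`; any other duplicate is an
    error.  Maximal runs of elements that are consecutive and equally
    oriented in both genomes are merged into single signed blocks named
    ``B1..Bk`` (members retained on the returned orders).
    """
    dup_events: list[DuplicationEvent] = []
    tgt_blocks = list(target.blocks)
    counts: dict[str, int] = {}
    for n, _ in tgt_blocks:
        counts[n] = counts.get(n, 0) + 1
    src_names = set(source.names)
    for name, c in counts.items():
        if c == 1:
            continue
        if c > 2 or source.names.count(name) != 1:
            raise ValueError(f"unresolvable duplicate block {name!r}; curate manually")
        idx = [i for i, (n, _) in enumerate(tgt_blocks) if n == name]
        ntgt = len(tgt_blocks)
        gap = idx[1] - idx[0]
        if target.circular:
            gap = min(gap, ntgt - gap)
        # tandem means the two copies form a contiguous duplicated run,
        # possibly as part of a multi-gene duplication (e.g. two genes
        # duplicated together); allow a small separation
        if gap > 3:
            raise ValueError(f"non-tandem duplicate block {name!r}; curate manually")
        del tgt_blocks[idx[1]]
        dup_events.append(DuplicationEvent(block=name))

    common = src_names & {n for n, _ in tgt_blocks}
    src = [(n, s) for n, s in source.blocks if n in common]
    tgt = [(n, s) for n, s in tgt_blocks if n in common]

    # rename source to signed identity, express target in that numbering
    number = {n: i + 1 for i, (n, _) in enumerate(src)}
    sign_of = {n: s for n, s in src}
    tgt_perm = [number[n] * s * sign_of[n] for n, s in tgt]

    # merge maximal common strips
    strips: list[list[int]] = []
    for x in tgt_perm:
        if strips and (
            (x > 0 and strips[-1][-1] == x - 1 and strips[-1][-1] > 0)
            or (x < 0 and strips[-1][-1] == x + 1 and strips[-1][-1] < 0)
        ):
            strips[-1].append(x)
        else:
            strips.append([x])
    # a strip in the target corresponds to a contiguous ascending run in source
    runs: list[tuple[int, int]] = []  # (lo, hi) in source numbering
    for st in strips:
        vals = [abs(v) for v in st]
        runs.append((min(vals), max(vals)))
    runs_sorted = sorted(runs)
    block_of: dict[int, str] = {}
    members: dict[str, list[tuple[str, int]]] = {}
    rev_number = {v: k for k, v in number.items()}
    for bi, (lo, hi) in enumerate(runs_sorted, start=1):
        name = f"B{bi}"
        for v in range(lo, hi + 1):
            block_of[v] = name
        members[name] = [(rev_number[v], sign_of[rev_number[v]]) for v in range(lo, hi + 1)]

    def blockify(perm_names: list[tuple[str, int]], is_target: bool) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for n, s in perm_names:
            v = number[n]
            b = block_of[v]
            eff = s * sign_of[n]  # orientation relative to source
            bsign = 1 if eff > 0 else -1
            if out and out[-1][0] == b:
                continue
            out.append((b, bsign if is_target else 1))
        return out

    src_out = blockify(src, is_target=False)
    tgt_out = blockify(tgt, is_target=True)

    def locate_repeat(order: SignedGeneOrder) -> str | None:
        if order.repeat_block is None:
            return None
        v = number.get(order.repeat_block)
        return block_of.get(v) if v is not None else None

    src_order = SignedGeneOrder(
        src_out,
        circular=source.circular,
        repeat_block=locate_repeat(source),
        orientation_flag=source.orientation_flag,
        members=members,
    )
    tgt_order = SignedGeneOrder(
        tgt_out,
        circular=target.circular,
        repeat_block=locate_repeat(target) or locate_repeat(source),
        orientation_flag=target.orientation_flag,
        members=members,
    )
    return src_order, tgt_order, dup_events


# ---------------------------------------------------------------------------
# breakpoints and permutations


def breakpoint_count(source: SignedGeneOrder, target: SignedGeneOrder) -> int:
    """Number of signed adjacencies of ``source`` not present in ``target``.

    Zero iff the two circular orders are equivalent up to rotation and
    reflection (strand choice).
    """
    if set(source.names) != set(target.names):
        raise ValueError("orders must share one alphabet; run collapse_to_blocks first")
    return len(source.adjacency_set() - target.adjacency_set())


def to_permutation(source: SignedGeneOrder, target: SignedGeneOrder) -> tuple[int, ...]:
    """Express target as a signed permutation with source as the identity,
    linearizing circular orders at the source's first block."""
    source._require_unique()
    target._require_unique()
    if set(source.names) != set(target.names):
        raise ValueError("orders must share one alphabet")
    src, tgt = source, target
    if source.circular and target.circular:
        tgt = target.anchored_to(source)
    number = {n: i + 1 for i, (n, _) in enumerate(src.blocks)}
    sign_of = {n: s for n, s in src.blocks}
    return tuple(number[n] * s * sign_of[n] for n, s in tgt.blocks)


def _cycles(perm: tuple[int, ...]) -> int:
    """Cycle count via explicit black/gray edge traversal."""
    n = len(perm)
    # point sequence with frame
    pts = [0]
    for x in perm:
        pts.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    pts.append(2 * n + 1)
    # black edges join pts[2i+1] -- pts[2i+2] for i in 0..n-1?  With frame,
    # breakpoint positions are between consecutive elements: pairs
    # (pts[0],pts[1]) is inside frame..no. Black edges: (pts[2i], pts[2i+1])
    # for i = 0..n  (element boundaries).
    m = n + 1  # number of black edges
    pos = {v: i for i, v in enumerate(pts)}
    partner_black = {}
    for i in range(m):
        a, b = pts[2 * i], pts[2 * i + 1]
        partner_black[a] = b
        partner_black[b] = a
    seen: set[int] = set()
    cycles = 0
    for v0 in pts:
        if v0 in seen:
            continue
        cycles += 1
        v = v0
        while v not in seen:
            seen.add(v)
            w = partner_black[v]
            seen.add(w)
            v = w + 1 if w % 2 == 0 else w - 1  # gray edge
    return cycles


def _lower_bound(perm: tuple[int, ...]) -> int:
    return len(perm) + 1 - _cycles(perm)


_IDENTITY_CACHE: dict[int, tuple[int, ...]] = {}


def _identity(n: int) -> tuple[int, ...]:
    if n not in _IDENTITY_CACHE:
        _IDENTITY_CACHE[n] = tuple(range(1, n + 1))
    return _IDENTITY_CACHE[n]


def _rev(perm: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    return perm[:i] + tuple(-v for v in reversed(perm[i : j + 1])) + perm[j + 1 :]


def reversal_distance_perm(perm: tuple[int, ...], cap: int = 20) -> int:
    """Exact signed reversal distance of a linear permutation to identity."""
    n = len(perm)
    if n > cap:
        raise ValueError(
            f"order length {n} exceeds exact-search cap {cap}; "
            "use infer_inversion_scenario with a bound"
        )
    ident = _identity(n)
    if perm == ident:
        return 0
    bound = _lower_bound(perm)
    while True:
        found = _ida_search(perm, 0, bound, ident)
        if found:
            return bound
        bound += 1


def _ida_search(perm, g, bound, ident) -> bool:
    h = _lower_bound(perm)
    if g + h > bound:
        return False
    if perm == ident:
        return True
    n = len(perm)
    for i in range(n):
        for j in range(i, n):
            child = _rev(perm, i, j)
            if child == perm:
                continue
            if _ida_search(child, g + 1, bound, ident):
                return True
    return False


def reversal_distance(source: SignedGeneOrder, target: SignedGeneOrder, cap: int = 20) -> int:
    """Minimal number of reversals transforming source into target (exact)."""
    perm = to_permutation(source, target)
    return reversal_distance_perm(perm, cap=cap)


# ---------------------------------------------------------------------------
# scenario inference


def _enumerate_scenarios(perm, bound, ident, cap):
    """All reversal sequences of length == bound from perm to identity,
    in lexicographic (leftmost endpoint, interval length) order, up to cap."""
    results: list[list[tuple[int, int]]] = []

    def dfs(p, g, path):
        if len(results) >= cap:
            return
        if p == ident:
            if g == bound:
                results.append(list(path))
            return
        if g + _lower_bound(p) > bound:
            return
        n = len(p)
        for i in range(n):
            for j in range(i, n):
                child = _rev(p, i, j)
                if child == p:
                    continue
                path.append((i, j))
                dfs(child, g + 1, path)
                path.pop()
                if len(results) >= cap:
                    return

    dfs(perm, 0, [])
    return results


def infer_inversion_scenario(
    source: SignedGeneOrder,
    target: SignedGeneOrder,
    max_events: int = 12,
    co_optima_cap: int = 64,
    cap: int = 20,
) -> ScenarioResult:
    """One minimum-length inversion scenario from source to target.

    Events are inclusive index intervals in the *current* order as the
    scenario is replayed left to right.  An event is flagged
    ``spans_repeat`` when its interval contains the block carrying the
    large repeat; the orientation trajectory starts from the source's
    orientation flag and toggles IR<->DR at each repeat-spanning event.
    All co-optimal scenarios are enumerated up to ``co_optima_cap``.
    """
    perm = to_permutation(source, target)
    bk = breakpoint_count(source, target) if source.circular == target.circular else 0
    try:
        dist = reversal_distance_perm(perm, cap=cap)
    except ValueError:
        raise
    if dist > max_events:
        return ScenarioResult(
            events=[],
            distance=dist,
            breakpoints_initial=bk,
            orientation_trajectory=[source.orientation_flag],
            optimal=False,
            lower_bound=_lower_bound(perm),
        )
    ident = _identity(len(perm))
    # scenarios transform target -> source-identity; we want source -> target,
    # which is the reverse sequence applied to the source.  A reversal is its
    # own inverse, so reverse the event list.
    raw = _enumerate_scenarios(perm, dist, ident, co_optima_cap)
    scenarios = [list(reversed(path)) for path in raw]
    scenarios.sort()

    def annotate(path):
        blocks = list(source.blocks)
        events = []
        traj = [source.orientation_flag]
        rb = source.repeat_block
        for k, (i, j) in enumerate(path):
            spans = False
            if rb is not None:
                names = [n for n, _ in blocks[i : j + 1]]
                spans = rb in names
            events.append(InversionEvent(interval=(i, j), spans_repeat=spans, label=f"E{k + 1}"))
            blocks = apply_reversal(blocks, i, j)
            if spans and traj[-1] in ("IR", "DR"):
                traj.append("DR" if traj[-1] == "IR" else "IR")
            elif traj[-1] in ("IR", "DR"):
                traj.append(traj[-1])
        return events, traj, blocks

    if not scenarios:  # distance 0
        return ScenarioResult(
            events=[],
            distance=0,
            breakpoints_initial=bk,
            orientation_trajectory=[source.orientation_flag],
            co_optima=[],
        )

    best_events, traj, final_blocks = annotate(scenarios[0])
    # replay check: final order must equal the (anchored) target
    tgt = target.anchored_to(source) if target.circular else target
    number = {n: i for i, (n, _) in enumerate(source.blocks)}
    assert [n for n, _ in final_blocks] == [n for n, _ in tgt.blocks] and [
        s for _, s in final_blocks
    ] == [s for _, s in tgt.blocks], "scenario replay failed to reproduce target"
    del number
    co = [annotate(p)[0] for p in scenarios[1:]]
    return ScenarioResult(
        events=best_events,
        distance=dist,
        breakpoints_initial=bk,
        orientation_trajectory=traj,
        co_optima=co,
    )


# ---------------------------------------------------------------------------
# parsimony placement on a fixed tree


def _expand_interval(order: SignedGeneOrder, blocks: list[tuple[str, int]], i: int, j: int) -> frozenset:
    """Underlying gene names covered by blocks[i..j] (block alphabets are
    pair-specific, so signatures are compared on the gene level)."""
    genes: set[str] = set()
    for name, _s in blocks[i : j + 1]:
        if order.members and name in order.members:
            genes.update(g for g, _ in order.members[name])
        else:
            genes.add(name)
    return frozenset(genes)


def event_signature(order: SignedGeneOrder, events: list[InversionEvent], k: int) -> tuple:
    """Characterize event k of an event list by the set of genes its
    interval covers in the pre-event order, plus its repeat flag."""
    blocks = list(order.blocks)
    for ev in events[:k]:
        blocks = apply_reversal(blocks, *ev.interval)
    i, j = events[k].interval
    return (_expand_interval(order, blocks, i, j), events[k].spans_repeat)


def place_events_on_tree(
    scenarios: dict[str, ScenarioResult],
    source_orders: dict[str, SignedGeneOrder],
    tree,
) -> dict[str, list]:
    """Assign pairwise-inferred events to tree branches by parsimony.

    ``scenarios`` maps tip name -> ScenarioResult from a common ancestral
    order to that tip; ``source_orders`` maps tip -> the (collapsed)
    ancestral order used for that pair.  At each internal node, an event
    whose signature opens some co-optimal scenario of *every* descendant
    tip is pushed onto that node's branch (the deepest branch consistent
    with all carriers); remaining events land on terminal branches.

    Returns branch-id (child-node label) -> list of (signature, event).
    """
    # candidate scenarios per tip: chosen plus co-optima, as signature lists
    cands: dict[str, list[list[tuple]]] = {}
    for tip, sc in scenarios.items():
        order = source_orders[tip]
        variants = [sc.events] + list(sc.co_optima)
        sig_lists = []
        for events in variants:
            sig_lists.append([
                (event_signature(order, events, k), events[k]) for k in range(len(events))
            ])
        cands[tip] = sig_lists or [[]]

    placements: dict[str, list] = {}

    def walk(node):
        tips = [t for t in node.leaf_names() if t in cands]
        if len(tips) > 1:
            while True:
                first_sigs = [
                    {lst[0][0] for lst in cands[t] if lst} for t in tips
                ]
                shared = set.intersection(*first_sigs) if all(first_sigs) else set()
                if not shared:
                    break
                sig = sorted(shared, key=lambda s: (sorted(s[0]), s[1]))[0]
                example = None
                for t in tips:
                    keep = [lst for lst in cands[t] if lst and lst[0][0] == sig]
                    example = example or keep[0][0]
                    cands[t] = [lst[1:] for lst in keep]
                placements.setdefault(node.label, []).append(example)
        for child in node.children:
            walk(child)

    walk(tree)
    for tip, variants in cands.items():
        rest = variants[0]
        if rest:
            placements.setdefault(tip, []).extend(rest)
    return placements


# ---------------------------------------------------------------------------
# exchange format (one genome per line: ">name" header then signed block names)


def write_orders(orders: dict[str, SignedGeneOrder], path) -> None:
    with open(path, "w") as fh:
        for name, order in orders.items():
            fh.write(f">{name}")
            if order.orientation_flag != "none":
                fh.write(f" orientation={order.orientation_flag}")
            fh.write("\n")
            fh.write(" ".join(("" if s > 0 else "-") + n for n, s in order.blocks))
            fh.write(" $\n" if not order.circular else " @\n")


def read_orders(path) -> dict[str, SignedGeneOrder]:
    out: dict[str, SignedGeneOrder] = {}
    name = None
    flag = "none"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                head = line[1:].split()
                name = head[0]
                flag = "none"
                for tok in head[1:]:
                    if tok.startswith("orientation="):
                        flag = tok.split("=", 1)[1]
                continue
            toks = line.split()
            circular = toks[-1] == "@"
            if toks[-1] in ("@", "$"):
                toks = toks[:-1]
            blocks = []
            for tok in toks:
                if tok.startswith("-"):
                    blocks.append((tok[1:], -1))
                else:
                    blocks.append((tok.lstrip("+"), 1))
            rb = REPEAT_BLOCK if REPEAT_BLOCK in (b[0] for b in blocks) else None
            out[name] = SignedGeneOrder(
                blocks, circular=circular, repeat_block=rb, orientation_flag=flag
            )
    return out
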