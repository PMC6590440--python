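"""Gene/intron content scoring and parsimony mapping of losses.

Every gene in every genome is scored intact / pseudogene / absent
(introns: present / absent), assembled into a species-by-element matrix
over a fixed land-plant catalog, and losses are placed on a given
phylogeny with a weighted (Sankoff) parsimony dynamic program.

Scoring rules: a gene is a pseudogene when its reading frame carries a
frameshift (summed exon length not divisible by 3), when its translated
length falls below a configurable fraction of the cross-taxon reference
length ("substantial truncation"), or — in taxa known to lack U-to-C
RNA editing, where a genomic stop cannot be rescued at the transcript
level — when the frame contains an internal stop codon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from plastevol.io import GeneFeature, PlastomeRecord
from plastevol.trees import Node

__all__ = [
    "ContentMatrix",
    "LossEvents",
    "DEFAULT_COSTS",
    "load_catalog",
    "score_gene_status",
    "build_content_matrix",
    "reconstruct_losses",
    "replay_events",
    "sankoff_cost",
]

PLASTID_CODE = 11  # plastid/bacterial genetic code

STATES = ("intact", "pseudogene", "absent")

# quasi-Dollo: degradation is cheap and ordered, regain is implausible
DEFAULT_COSTS: dict[tuple[str, str], float] = {
    ("intact", "intact"): 0,
    ("pseudogene", "pseudogene"): 0,
    ("absent", "absent"): 0,
    ("intact", "pseudogene"): 1,
    ("pseudogene", "absent"): 1,
    ("intact", "absent"): 2,
    ("pseudogene", "intact"): 10,
    ("absent", "intact"): 10,
    ("absent", "pseudogene"): 10,
}


def load_catalog() -> pd.DataFrame:
    """The shipped land-plant element catalog (element, category, host)."""
    path = Path(__file__).parent / "data" / "plastid_catalog.tsv"
    rows = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rows.append((row[0], row[1], row[2] if len(row) > 2 else ""))
    return pd.DataFrame(rows, columns=["element", "category", "host"]).set_index("element")


@dataclass
class ContentMatrix:
    """Species x element state matrix plus per-category intact totals."""

    states: pd.DataFrame  # rows: taxa, columns: elements
    categories: dict[str, str]

    @property
    def taxa(self) -> list[str]:
        return list(self.states.index)

    @property
    def elements(self) -> list[str]:
        return list(self.states.columns)

    def totals(self) -> pd.DataFrame:
        """Per-taxon counts of intact genes / present introns by category."""
        ok = self.states.isin(["intact", "present"])
        rows = {}
        for cat in ("protein", "rRNA", "tRNA", "intron"):
            cols = [e for e in self.elements if self.categories.get(e) == cat]
            rows[cat] = ok[cols].sum(axis=1)
        df = pd.DataFrame(rows)
        df["genes"] = df["protein"] + df["rRNA"] + df["tRNA"]
        return df

    def to_tsv(self, path) -> None:
        self.states.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, categories: dict[str, str] | None = None) -> "ContentMatrix":
        states = pd.read_csv(path, sep="\t", index_col=0)
        if categories is None:
            cat = load_catalog()
            categories = {e: cat.loc[e, "category"] for e in states.columns if e in cat.index}
        return cls(states=states, categories=categories)


@dataclass
class LossEvents:
    """Parsimony reconstruction of content changes on a fixed tree."""

    # branch id (child-node label) -> list of (element, event-type, from, to)
    events: dict[str, list[tuple[str, str, str, str]]]
    cost: float
    per_element_cost: dict[str, float]
    # element -> list of optimal assignments (node label -> state)
    scenarios: dict[str, list[dict[str, str]]]
    root_states: dict[str, str]
    unambiguous: set[tuple[str, str]] = field(default_factory=set)  # (branch, element)

    def branch_events(self, branch: str) -> list[tuple[str, str, str, str]]:
        return self.events.get(branch, [])

    def element_events(self, element: str) -> list[tuple[str, str]]:
        """(branch, event-type) pairs for one element in the chosen scenario."""
        out = []
        for br, evs in self.events.items():
            for el, ev, _a, _b in evs:
                if el == element:
                    out.append((br, ev))
        return out


# ---------------------------------------------------------------------------
# scoring


def score_gene_status(
    feature: GeneFeature | None,
    record: PlastomeRecord | None,
    reference_length: float | None = None,
    no_uc_editing: bool = False,
    truncation_fraction: float = 0.5,
) -> str:
    """Score one annotated gene as intact / pseudogene / absent.

    ``reference_length`` is the cross-taxon median spliced CDS length in
    bp; translations shorter than ``truncation_fraction`` of its amino
    acid equivalent are called pseudogenes.  With ``no_uc_editing`` an
    internal stop codon is diagnostic of pseudogenization because the
    taxon cannot repair genomic stops by U-to-C editing.
    """
    if feature is None:
        return "absent"
    if feature.kind in ("rRNA", "tRNA"):
        return "intact"
    if feature.kind == "intron":
        return "present"
    seq = record.feature_sequence(feature)
    if len(seq) % 3 != 0:
        return "pseudogene"  # frameshift
    aa = str(Seq(seq).translate(table=PLASTID_CODE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if no_uc_editing and "*" in aa:
        return "pseudogene"  # internal stop, not rescuable by editing
    if reference_length is not None:
        ref_aa = reference_length / 3.0 - 1.0
        if ref_aa > 0 and len(aa.rstrip("*").split("*")[0] if no_uc_editing else aa) < truncation_fraction * ref_aa:
            return "pseudogene"
    return "intact"


def build_content_matrix(
    records: list[PlastomeRecord],
    catalog: pd.DataFrame | None = None,
    no_uc_editing_taxa: set[str] | frozenset[str] = frozenset(),
    truncation_fraction: float = 0.5,
    strict: bool = False,
) -> ContentMatrix:
    """Score every catalog element in every record.

    Reference lengths for the truncation rule are cross-record medians
    of the spliced lengths of intact-frame annotations.  Intron presence
    additionally requires the host gene not to be absent.  With
    ``strict``, annotated gene names outside the catalog raise.
    """
    if catalog is None:
        catalog = load_catalog()
    categories = {e: catalog.loc[e, "category"] for e in catalog.index}
    hosts = {e: catalog.loc[e, "host"] for e in catalog.index if catalog.loc[e, "category"] == "intron"}

    feature_of: dict[str, dict[str, GeneFeature]] = {}
    for rec in records:
        fmap: dict[str, GeneFeature] = {}
        for f in rec.features:
            if f.copy_index > 0:
                continue
            if strict and f.kind != "ORF" and f.name not in catalog.index:
                raise KeyError(f"{rec.id}: annotated element {f.name!r} not in catalog")
            fmap.setdefault(f.name, f)
        feature_of[rec.id] = fmap

    ref_lengths: dict[str, float] = {}
    for el in catalog.index:
        if categories[el] != "protein":
            continue
        lens = [
            feature_of[r.id][el].exon_length
            for r in records
            if el in feature_of[r.id] and feature_of[r.id][el].exon_length % 3 == 0
        ]
        if lens:
            lens.sort()
            ref_lengths[el] = lens[len(lens) // 2]

    data = {}
    for rec in records:
        col = {}
        noed = rec.id in no_uc_editing_taxa
        for el in catalog.index:
            feat = feature_of[rec.id].get(el)
            state = score_gene_status(
                feat, rec, ref_lengths.get(el), no_uc_editing=noed, truncation_fraction=truncation_fraction
            )
            col[el] = state
        # intron presence requires the host gene
        for el, host in hosts.items():
            if col.get(host) == "absent" and col[el] == "present":
                col[el] = "absent"
            if col[el] == "present":
                pass
            elif col[el] == "intact":
                col[el] = "present"
        data[rec.id] = col
    states = pd.DataFrame(data).T
    states = states[list(catalog.index)]
    # introns use a two-state vocabulary
    for el in hosts:
        states[el] = states[el].replace({"intact": "present", "pseudogene": "absent"})
    return ContentMatrix(states=states, categories=categories)


# ---------------------------------------------------------------------------
# Sankoff parsimony


def _element_states(matrix: ContentMatrix, element: str) -> tuple[dict[str, str], bool]:
    col = matrix.states[element]
    is_intron = matrix.categories.get(element) == "intron"
    obs = {}
    for taxon, st in col.items():
        # two-state characters (introns, derived presence/absence traits)
        # ride on the three-state machinery as intact/absent
        st = {"present": "intact"}.get(st, st)
        if st not in STATES:
            raise ValueError(f"{element}: unknown state {st!r} for {taxon}")
        obs[taxon] = st
    return obs, is_intron


def sankoff_cost(
    tip_states: dict[str, str],
    tree: Node,
    costs: dict[tuple[str, str], float] = DEFAULT_COSTS,
    states: tuple[str, ...] = STATES,
) -> float:
    """Minimum weighted parsimony cost of one character on a rooted tree."""
    INF = float("inf")
    table: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            st = tip_states[node.label]
            table[id(node)] = {s: (0.0 if s == st else INF) for s in states}
        else:
            table[id(node)] = {
                s: sum(
                    min(costs[(s, t)] + table[id(c)][t] for t in states)
                    for c in node.children
                )
                for s in states
            }
    return min(table[id(tree)].values())


def _sankoff_enumerate(
    tip_states: dict[str, str],
    tree: Node,
    costs: dict[tuple[str, str], float],
    states: tuple[str, ...],
    cap: int,
) -> tuple[float, list[dict[str, str]]]:
    """All minimum-cost internal-state assignments, up to ``cap``."""
    INF = float("inf")
    table: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            st = tip_states[node.label]
            table[id(node)] = {s: (0.0 if s == st else INF) for s in states}
        else:
            table[id(node)] = {
                s: sum(
                    min(costs[(s, t)] + table[id(c)][t] for t in states)
                    for c in node.children
                )
                for s in states
            }
    best = min(table[id(tree)].values())

    def enumerate_node(node: Node, state: str) -> list[dict[str, str]]:
        """All optimal assignments of node's subtree given node's state."""
        if node.is_leaf:
            return [{node.label: state}]
        options_per_child: list[list[dict[str, str]]] = []
        for child in node.children:
            target = min(costs[(state, t)] + table[id(child)][t] for t in states)
            child_opts: list[dict[str, str]] = []
            for t in states:
                if costs[(state, t)] + table[id(child)][t] == target:
                    child_opts.extend(enumerate_node(child, t))
                if len(child_opts) >= cap:
                    break
            options_per_child.append(child_opts[:cap])
        combos: list[dict[str, str]] = [{node.label: state}]
        for child_opts in options_per_child:
            new: list[dict[str, str]] = []
            for base in combos:
                for opt in child_opts:
                    merged = dict(base)
                    merged.update(opt)
                    new.append(merged)
                    if len(new) >= cap:
                        break
                if len(new) >= cap:
                    break
            combos = new
        return combos

    results: list[dict[str, str]] = []
    for s in states:
        if table[id(tree)][s] == best:
            results.extend(enumerate_node(tree, s))
        if len(results) >= cap:
            break
    return best, results[:cap]


def reconstruct_losses(
    matrix: ContentMatrix,
    tree: Node,
    costs: dict[tuple[str, str], float] = DEFAULT_COSTS,
    co_optima_cap: int = 64,
) -> LossEvents:
    """Sankoff parsimony over every element; events reported per branch.

    Polytomies are handled natively by the dynamic program.  All
    minimum-cost assignments are enumerated (capped); branches on which
    every optimum implies the same event are marked unambiguous.
    """
    tips = set(tree.leaf_names())
    missing = set(matrix.taxa) - tips
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")

    events: dict[str, list[tuple[str, str, str, str]]] = {}
    scenarios: dict[str, list[dict[str, str]]] = {}
    per_cost: dict[str, float] = {}
    root_states: dict[str, str] = {}
    unambiguous: set[tuple[str, str]] = set()
    total = 0.0

    for element in matrix.elements:
        tip_states, _ = _element_states(matrix, element)
        cost, assigns = _sankoff_enumerate(tip_states, tree, costs, STATES, co_optima_cap)
        total += cost
        per_cost[element] = cost
        scenarios[element] = assigns
        chosen = assigns[0]
        root_states[element] = chosen[tree.label]

        def branch_changes(assign: dict[str, str]) -> set[tuple[str, str, str]]:
            out = set()
            for node in tree.postorder():
                if node.parent is None:
                    continue
                a, b = assign[node.parent.label], assign[node.label]
                if a != b:
                    out.add((node.label, a, b))
            return out

        chosen_changes = branch_changes(chosen)
        common = chosen_changes
        for alt in assigns[1:]:
            common = common & branch_changes(alt)
        for br, a, b in chosen_changes:
            if (a, b) in (("intact", "pseudogene"),):
                ev = "pseudogenization"
            elif b == "absent":
                ev = "loss"
            else:
                ev = "gain"
            events.setdefault(br, []).append((element, ev, a, b))
            if (br, a, b) in common:
                unambiguous.add((br, element))

    return LossEvents(
        events=events,
        cost=total,
        per_element_cost=per_cost,
        scenarios=scenarios,
        root_states=root_states,
        unambiguous=unambiguous,
    )


def replay_events(result: LossEvents, tree: Node) -> pd.DataFrame:
    """Walk the tree from the root applying the chosen events; returns the
    implied tip-state matrix (used to verify round-trip consistency)."""
    elements = list(result.root_states)
    tip_rows: dict[str, dict[str, str]] = {}

    def walk(node: Node, state_of: dict[str, str]):
        if node.parent is not None:
            for el, _ev, a, b in result.branch_events(node.label):
                assert state_of[el] == a, f"replay mismatch for {el} on {node.label}"
                state_of = dict(state_of)
                state_of[el] = b
        if node.is_leaf:
            tip_rows[node.label] = state_of
        for c in node.children:
            walk(c, state_of)

    walk(tree, dict(result.root_states))
    return pd.DataFrame(tip_rows).T[elements]
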