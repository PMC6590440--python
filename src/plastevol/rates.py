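"""Per-branch divergence estimation on a fixed topology.

Two reversible substitution models are provided behind a shared
maximum-likelihood engine (Felsenstein pruning with eigendecomposition
of the symmetrized generator):

* :class:`CodonModel` — an MG94-style codon model over the 61 sense
  codons of the plastid/bacterial genetic code.  Only single-nucleotide
  codon changes have nonzero rate; a synonymous i->j change has rate
  ``theta_class(i,j) * pi_nt(target)`` and a nonsynonymous change is
  additionally multiplied by a per-branch omega (a "local" model).
  Exchangeabilities may be tied into classes by a six-digit string over
  the nucleotide pairs (AC, AG, AT, CG, CT, GT), e.g. ``"012232"``.
  Codon frequencies come from the F3x4 construction (per-position
  nucleotide frequencies, never optimized).  Per-branch synonymous
  divergence is reported as

      dS = t * [syn flux under the branch's omega] / [syn flux at omega = 1]

  with both fluxes evaluated at the fitted exchangeabilities and
  frequencies — the standard MG94 synonymous-site scaling.

* :class:`NucleotideModel` — GTR with discrete-Gamma rate variation
  (4 mean-one categories) and a proportion of invariant sites; branch
  divergence d is reported as expected substitutions per site,
  ``t * (1 - p_inv)``.

Fitting is coordinate ascent: per-branch Brent line searches on branch
length (and omega, for the codon model) against spectral likelihood
coefficients, alternating with Nelder-Mead over the global parameters,
until the log-likelihood improves by less than ``tol``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from Bio.Data import CodonTable

from plastevol.io import Alignment
from plastevol.trees import Node, parse_newick, to_newick

__all__ = [
    "RateClassSpec",
    "RateTree",
    "RateComparison",
    "parse_rate_class",
    "trim_alignment",
    "CodonModel",
    "CodonResults",
    "NucleotideModel",
    "NucleotideResults",
    "estimate_branch_lengths_codon",
    "estimate_branch_lengths_nt",
    "compare_rates",
]

NT = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NT)}
PAIR_ORDER = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
PLASTID_TABLE = CodonTable.unambiguous_dna_by_id[11]


# ---------------------------------------------------------------------------
# rate-class strings


@dataclass(frozen=True)
class RateClassSpec:
    """Tying pattern for the six GTR exchangeabilities.

    ``class_string`` maps the nucleotide pairs (AC, AG, AT, CG, CT, GT),
    in that order, to shared parameter classes; classes are renumbered
    densely from zero.  ``"012345"`` is full GTR, ``"000000"`` a single
    shared exchangeability.
    """

    class_string: str
    assignment: tuple[int, ...]
    free_count: int

    def pair_classes(self) -> dict[tuple[str, str], int]:
        return {PAIR_ORDER[i]: c for i, c in enumerate(self.assignment)}


def parse_rate_class(class_string: str) -> RateClassSpec:
    if len(class_string) != 6 or not class_string.isdigit():
        raise ValueError(f"rate-class string must be 6 digits, got {class_string!r}")
    raw = [int(c) for c in class_string]
    dense: dict[int, int] = {}
    assignment = []
    for c in raw:
        if c not in dense:
            dense[c] = len(dense)
        assignment.append(dense[c])
    return RateClassSpec(class_string=class_string, assignment=tuple(assignment), free_count=len(dense))


# ---------------------------------------------------------------------------
# alignment trimming


def trim_alignment(aln: Alignment, mode: str | None = None, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns (codon-triplets in codon mode) whose gap fraction
    exceeds ``max_gap_fraction``.  A deliberately simple column filter:
    block-conservation heuristics of full trimming tools are not
    replicated, and pre-trimmed matrices pass through unchanged."""
    mode = mode or aln.datatype
    rows = aln.rows
    n = len(rows)
    width = 3 if mode == "codon" else 1
    keep: list[int] = []
    for start in range(0, aln.n_sites, width):
        gaps = sum(1 for r in rows if "-" in r[start : start + width] or "?" in r[start : start + width])
        if gaps / n <= max_gap_fraction:
            keep.append(start)
    if not keep:
        raise ValueError("trimming removed every column")
    new_rows = ["".join(r[s : s + width] for s in keep) for r in rows]
    return Alignment(list(aln.taxa), new_rows, aln.datatype)


# ---------------------------------------------------------------------------
# codon machinery


class _CodonSpace:
    """Static structure of the 61-codon state space under code 11."""

    def __init__(self) -> None:
        stops = set(PLASTID_TABLE.stop_codons)
        self.codons = [
            "".join(c) for c in itertools.product(NT, repeat=3) if "".join(c) not in stops
        ]
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.aa = {c: PLASTID_TABLE.forward_table[c] for c in self.codons}
        pairs_i, pairs_j, pair_cls, syn, tpos, tnt = [], [], [], [], [], []
        pair_class_index = {p: i for i, p in enumerate(PAIR_ORDER)}
        for i, ci in enumerate(self.codons):
            for pos in range(3):
                for b in NT:
                    if b == ci[pos]:
                        continue
                    cj = ci[:pos] + b + ci[pos + 1 :]
                    j = self.index.get(cj)
                    if j is None:
                        continue
                    key = tuple(sorted((ci[pos], b)))
                    pairs_i.append(i)
                    pairs_j.append(j)
                    pair_cls.append(pair_class_index[key])
                    syn.append(self.aa[ci] == self.aa[cj])
                    tpos.append(pos)
                    tnt.append(NT_INDEX[b])
        self.pairs_i = np.array(pairs_i)
        self.pairs_j = np.array(pairs_j)
        self.pair_cls = np.array(pair_cls)
        self.syn = np.array(syn, dtype=bool)
        self.tpos = np.array(tpos)
        self.tnt = np.array(tnt)
        self.n = len(self.codons)


_SPACE: _CodonSpace | None = None


def codon_space() -> _CodonSpace:
    global _SPACE
    if _SPACE is None:
        _SPACE = _CodonSpace()
    return _SPACE


def f3x4_frequencies(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position nucleotide frequencies and the implied sense-codon
    frequencies (F3x4)."""
    counts = np.ones((3, 4))  # +1 pseudocount keeps frequencies positive
    for row in rows:
        for k in range(0, len(row) - 2, 3):
            for pos in range(3):
                b = row[k + pos]
                if b in NT_INDEX:
                    counts[pos, NT_INDEX[b]] += 1
    pi_nt = counts / counts.sum(axis=1, keepdims=True)
    space = codon_space()
    pi = np.array(
        [pi_nt[0, NT_INDEX[c[0]]] * pi_nt[1, NT_INDEX[c[1]]] * pi_nt[2, NT_INDEX[c[2]]] for c in space.codons]
    )
    return pi_nt, pi / pi.sum()


def codon_generator(
    theta6: np.ndarray, omega: float, pi_nt: np.ndarray, spec: RateClassSpec
) -> tuple[np.ndarray, float, float]:
    """Unnormalized MG94 generator plus (total flux, synonymous flux).

    Fluxes are relative to the F3x4 codon frequencies; rates use the
    target-nucleotide frequency, which makes the chain reversible with
    respect to those codon frequencies.
    """
    space = codon_space()
    theta_by_pair = theta6[np.asarray(spec.assignment)]
    rates = theta_by_pair[space.pair_cls] * pi_nt[space.tpos, space.tnt]
    rates = np.where(space.syn, rates, rates * omega)
    Q = np.zeros((space.n, space.n))
    Q[space.pairs_i, space.pairs_j] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    _, pi = f3x4_from_pi_nt(pi_nt)
    flux = pi[space.pairs_i] * rates
    return Q, float(flux.sum()), float(flux[space.syn].sum())


def f3x4_from_pi_nt(pi_nt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    space = codon_space()
    pi = np.array(
        [pi_nt[0, NT_INDEX[c[0]]] * pi_nt[1, NT_INDEX[c[1]]] * pi_nt[2, NT_INDEX[c[2]]] for c in space.codons]
    )
    return pi_nt, pi / pi.sum()


def synonymous_fraction(theta6: np.ndarray, omega: float, pi_nt: np.ndarray, spec: RateClassSpec) -> float:
    _, total, syn = codon_generator(theta6, omega, pi_nt, spec)
    return syn / total


def ds_from_t(t: float, theta6: np.ndarray, omega: float, pi_nt: np.ndarray, spec: RateClassSpec) -> float:
    """Synonymous divergence for a branch of length t (expected
    substitutions per codon) under the MG94 synonymous-site scaling."""
    if t == 0:
        return 0.0
    frac_omega = synonymous_fraction(theta6, omega, pi_nt, spec)
    frac_neutral = synonymous_fraction(theta6, 1.0, pi_nt, spec)
    return t * frac_omega / frac_neutral


def gtr_generator(theta6: np.ndarray, pi: np.ndarray, spec: RateClassSpec) -> np.ndarray:
    Q = np.zeros((4, 4))
    for (a, b), cls in zip(PAIR_ORDER, spec.assignment):
        i, j = NT_INDEX[a], NT_INDEX[b]
        Q[i, j] = theta6[cls] * pi[j]
        Q[j, i] = theta6[cls] * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = -(pi * np.diag(Q)).sum()
    return Q / flux  # unit expected substitutions per site per unit t


# ---------------------------------------------------------------------------
# spectral helpers


def spectral(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a pi-reversible generator.

    Returns (lam, U, V) with P(t) = U @ diag(exp(lam t)) @ V.
    """
    d = np.sqrt(np.maximum(pi, 1e-300))
    B = (Q * d[:, None]) / d[None, :]
    B = (B + B.T) / 2.0
    lam, W = np.linalg.eigh(B)
    U = W / d[:, None]
    V = W.T * d[None, :]
    return lam, U, V


def transition_matrix(lam, U, V, t: float) -> np.ndarray:
    P = (U * np.exp(lam * t)) @ V
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# pattern compression


def _codon_patterns(aln: Alignment, taxa_order: list[str]):
    space = codon_space()
    rows = dict(zip(aln.taxa, aln.rows))
    ncod = aln.n_codons
    mat = np.full((len(taxa_order), ncod), -1, dtype=np.int32)
    stops = set(PLASTID_TABLE.stop_codons)
    for ti, taxon in enumerate(taxa_order):
        row = rows[taxon]
        for k in range(ncod):
            cod = row[3 * k : 3 * k + 3]
            if cod in space.index:
                mat[ti, k] = space.index[cod]
            elif cod in stops:
                if k < ncod - 1:
                    raise ValueError(f"internal stop codon {cod} in {taxon}, codon {k + 1}")
                mat[ti, k] = -1  # terminal stop tolerated as missing
    pat, counts = np.unique(mat.T, axis=0, return_counts=True)
    return pat.T, counts.astype(float)


def _nt_patterns(aln: Alignment, taxa_order: list[str]):
    rows = dict(zip(aln.taxa, aln.rows))
    mat = np.full((len(taxa_order), aln.n_sites), -1, dtype=np.int32)
    for ti, taxon in enumerate(taxa_order):
        for k, b in enumerate(rows[taxon]):
            mat[ti, k] = NT_INDEX.get(b, -1)
    pat, counts = np.unique(mat.T, axis=0, return_counts=True)
    return pat.T, counts.astype(float)


# ---------------------------------------------------------------------------
# the pruning engine


class _Engine:
    """Pruning likelihood over a fixed topology with per-branch transition
    matrices, shared by the codon and nucleotide models.

    A binary root is collapsed (the two root edges merged) so every
    branch length is identifiable under the reversible models.
    """

    def __init__(self, tree: Node, patterns: np.ndarray, counts: np.ndarray, n_states: int,
                 taxa_order: list[str] | None = None):
        taxa_order = taxa_order or tree.leaf_names()
        self.tree = _collapse_binary_root(tree.copy())
        self.taxa = self.tree.leaf_names()
        self.patterns = patterns
        self.counts = counts
        self.S = n_states
        self.nodes = list(self.tree.postorder())
        self.branches = [n for n in self.nodes if n.parent is not None]
        row_of = {label: i for i, label in enumerate(taxa_order)}
        npat = patterns.shape[1]
        self._leaf_partials = {}
        for label in self.taxa:
            states = patterns[row_of[label]]
            part = np.zeros((npat, n_states))
            ok = states >= 0
            part[ok, states[ok]] = 1.0
            part[~ok, :] = 1.0
            self._leaf_partials[label] = part

    def loglik(self, P_of_branch: dict[str, np.ndarray], pi: np.ndarray,
               weights=None, pinv: float = 0.0, pinv_partial=None) -> float:
        """Sum over patterns of log site likelihood.

        ``P_of_branch`` maps branch id -> either one P matrix or a list
        per rate category; ``weights`` are category weights.
        """
        per_cat = isinstance(next(iter(P_of_branch.values())), (list, tuple))
        cats = len(next(iter(P_of_branch.values()))) if per_cat else 1
        w = weights if weights is not None else [1.0] * cats
        npat = self.patterns.shape[1]
        cat_logs = np.full((cats, npat), -np.inf)
        for c in range(cats):
            down, scale = self._down_pass({b: (P[c] if per_cat else P) for b, P in P_of_branch.items()})
            lk = down[id(self.tree)] @ pi
            cat_logs[c] = np.log(np.maximum(lk, 1e-300)) + scale + np.log(w[c])
        if pinv > 0.0 and pinv_partial is not None:
            with np.errstate(divide="ignore"):
                log_inv = np.where(
                    pinv_partial > 0,
                    np.log(pinv) + np.log(np.maximum(pinv_partial, 1e-300)),
                    -np.inf,
                )
            cat_logs = np.vstack([cat_logs, log_inv])
        mx = cat_logs.max(axis=0)
        log_l = mx + np.log(np.exp(cat_logs - mx).sum(axis=0))
        return float(self.counts @ log_l)

    def _down_pass(self, P_of_branch):
        npat = self.patterns.shape[1]
        down = {}
        scale = np.zeros(npat)
        for node in self.nodes:
            if node.is_leaf:
                down[id(node)] = self._leaf_partials[node.label]
            else:
                part = np.ones((npat, self.S))
                for child in node.children:
                    msg = down[id(child)] @ P_of_branch[child.label].T
                    part = part * msg
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                part = part / mx[:, None]
                scale = scale + np.log(mx)
                down[id(node)] = part
        return down, scale

    def edge_vectors(self, branch_label: str, P_of_branch, pi: np.ndarray):
        """(F, G, logscale) for one branch: site likelihood = sum_ab
        F[p,a] P_ab G[p,b] * exp(logscale[p])."""
        npat = self.patterns.shape[1]
        down = {}
        dscale = {}
        for node in self.nodes:
            if node.is_leaf:
                down[id(node)] = self._leaf_partials[node.label]
                dscale[id(node)] = np.zeros(npat)
            else:
                part = np.ones((npat, self.S))
                sc = np.zeros(npat)
                for child in node.children:
                    part = part * (down[id(child)] @ P_of_branch[child.label].T)
                    sc = sc + dscale[id(child)]
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                part /= mx[:, None]
                down[id(node)] = part
                dscale[id(node)] = sc + np.log(mx)
        # up-pass
        up = {id(self.tree): np.tile(pi, (npat, 1))}
        uscale = {id(self.tree): np.zeros(npat)}
        target = None
        for node in self.tree.preorder():
            for child in node.children:
                sib = np.ones((npat, self.S))
                ssc = np.zeros(npat)
                for other in node.children:
                    if other is child:
                        continue
                    sib = sib * (down[id(other)] @ P_of_branch[other.label].T)
                    ssc = ssc + dscale[id(other)]
                part = up[id(node)] * sib
                mx = part.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                part = part / mx[:, None]
                sc = uscale[id(node)] + ssc + np.log(mx)
                if child.label == branch_label:
                    target = (part, down[id(child)], sc + dscale[id(child)])
                # message across child's branch folds into child's "up"
                up[id(child)] = part @ P_of_branch[child.label]
                uscale[id(child)] = sc
        if target is None:
            raise KeyError(branch_label)
        return target


def _collapse_binary_root(root: Node) -> Node:
    if len(root.children) != 2:
        return root
    a, b = root.children
    if a.is_leaf and b.is_leaf:
        return root  # two-taxon tree: keep both edges
    donor, keep = (a, b) if not a.is_leaf else (b, a)
    new_root = Node(root.label, length=None)
    for c in donor.children:
        c.parent = new_root
        new_root.children.append(c)
    keep.length = (donor.length or 0.0) + (keep.length or 0.0)
    keep.parent = new_root
    new_root.children.append(keep)
    return new_root


# ---------------------------------------------------------------------------
# results containers


@dataclass
class RateTree:
    """A fixed topology with one divergence value per branch."""

    tree: Node
    values: dict[str, float]  # branch id (child-node label) -> value
    kind: str  # "dS" | "d"
    provenance: str = ""

    def terminal_value(self, species: str) -> float:
        if species not in self.values:
            raise KeyError(f"{species!r} is not a branch of this tree")
        return self.values[species]

    def to_newick(self) -> str:
        return to_newick(self.tree, lengths=self.values)


@dataclass
class RateComparison:
    """Terminal-branch divergence of a species in two trees and their ratio."""

    species: str
    duplicated_branch_value: float
    sc_branch_value: float
    ratio: float | None
    flagged: bool = False


def compare_rates(tree_dup: RateTree, tree_sc: RateTree, species: str) -> RateComparison:
    """Ratio of a species' terminal branch value between two rate trees
    (duplicated-gene partition over single-copy partition)."""
    dup = tree_dup.terminal_value(species)
    sc = tree_sc.terminal_value(species)
    if sc <= 0:
        return RateComparison(species, dup, sc, None, flagged=True)
    return RateComparison(species, dup, sc, dup / sc)


def _summary_table(title: str, rows: list[tuple], headers: tuple[str, ...]) -> str:
    widths = [max(len(str(h)), max((len(f"{r[i]:.4f}" if isinstance(r[i], float) else str(r[i])) for r in rows), default=0)) for i, h in enumerate(headers)]
    out = [title, "=" * (sum(widths) + 2 * len(widths))]
    out.append("  ".join(h.ljust(w) for h, w in zip(headers, widths)))
    out.append("-" * (sum(widths) + 2 * len(widths)))
    for r in rows:
        cells = [f"{v:.4f}" if isinstance(v, float) else str(v) for v in r]
        out.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    return "\n".join(out)


@dataclass
class CodonResults:
    """Fitted MG94 codon model: per-branch (t, omega, dS) and globals."""

    model: "CodonModel"
    loglik: float
    theta: np.ndarray
    branch_t: dict[str, float]
    branch_omega: dict[str, float]
    branch_ds: dict[str, float]
    pi_nt: np.ndarray
    n_iter: int = 0
    converged: bool = True

    def rate_tree(self) -> RateTree:
        return RateTree(
            tree=self.model.engine.tree,
            values=dict(self.branch_ds),
            kind="dS",
            provenance=f"MG94-{self.model.spec.class_string}/F3x4",
        )

    def branch_table(self) -> pd.DataFrame:
        rows = [
            (b, self.branch_t[b], self.branch_omega[b], self.branch_ds[b])
            for b in sorted(self.branch_t)
        ]
        return pd.DataFrame(rows, columns=["branch", "t", "omega", "dS"]).set_index("branch")

    def summary(self) -> str:
        head = (
            f"MG94 codon model ({self.model.spec.class_string}; F3x4)\n"
            f"n codons: {int(self.model.engine.counts.sum())}   "
            f"taxa: {len(self.model.engine.taxa)}   "
            f"log-likelihood: {self.loglik:.4f}\n"
            f"exchangeabilities: {np.round(self.theta, 4).tolist()}"
        )
        rows = [(b, self.branch_t[b], self.branch_omega[b], self.branch_ds[b]) for b in sorted(self.branch_t)]
        return head + "\n" + _summary_table("per-branch estimates", rows, ("branch", "t", "omega", "dS"))


@dataclass
class NucleotideResults:
    """Fitted GTR+Gamma+I model: per-branch divergence and globals."""

    model: "NucleotideModel"
    loglik: float
    theta: np.ndarray
    alpha: float | None
    p_inv: float
    branch_t: dict[str, float]
    pi: np.ndarray
    n_iter: int = 0
    converged: bool = True

    @property
    def branch_d(self) -> dict[str, float]:
        return {b: t * (1.0 - self.p_inv) for b, t in self.branch_t.items()}

    def rate_tree(self) -> RateTree:
        g = f"+G{self.model.gamma_categories}" if self.alpha is not None else ""
        i = "+I" if self.model.invariant else ""
        return RateTree(
            tree=self.model.engine.tree,
            values=dict(self.branch_d),
            kind="d",
            provenance=f"GTR{g}{i}",
        )

    def summary(self) -> str:
        head = (
            f"GTR{'+G' if self.alpha is not None else ''}{'+I' if self.model.invariant else ''} "
            f"nucleotide model\n"
            f"n sites: {int(self.model.engine.counts.sum())}   taxa: {len(self.model.engine.taxa)}   "
            f"log-likelihood: {self.loglik:.4f}\n"
            f"exchangeabilities: {np.round(self.theta, 4).tolist()}   "
            f"alpha: {self.alpha if self.alpha is None else round(self.alpha, 4)}   "
            f"p_inv: {self.p_inv:.4f}"
        )
        d = self.branch_d
        rows = [(b, self.branch_t[b], d[b]) for b in sorted(self.branch_t)]
        return head + "\n" + _summary_table("per-branch estimates", rows, ("branch", "t", "d"))


# ---------------------------------------------------------------------------
# models


class CodonModel:
    """MG94-style codon model on a fixed topology.

    Parameters
    ----------
    alignment : codon Alignment (length divisible by 3, no internal stops)
    tree : newick string or Node; branch lengths, if any, seed the fit
    rate_classes : six-digit exchangeability tying string or RateClassSpec
    """

    T_MAX = 30.0
    OMEGA_MAX = 20.0

    def __init__(self, alignment: Alignment, tree: str | Node, rate_classes: str | RateClassSpec = "012345"):
        if alignment.datatype != "codon":
            raise ValueError("CodonModel requires a codon alignment")
        self.alignment = alignment
        self.spec = rate_classes if isinstance(rate_classes, RateClassSpec) else parse_rate_class(rate_classes)
        root = parse_newick(tree) if isinstance(tree, str) else tree
        tips = set(root.leaf_names())
        if tips != set(alignment.taxa):
            raise ValueError(
                f"tree tips and alignment taxa differ: {sorted(tips ^ set(alignment.taxa))}"
            )
        taxa_order = root.copy().leaf_names()
        patterns, counts = _codon_patterns(alignment, taxa_order)
        self.engine = _Engine(root, patterns, counts, codon_space().n, taxa_order)
        self.pi_nt, self.pi = f3x4_frequencies(alignment.rows)

    @classmethod
    def from_files(cls, alignment_path, tree_path, rate_classes="012345") -> "CodonModel":
        from plastevol.io import read_alignment

        aln = read_alignment(alignment_path, datatype="codon")
        with open(tree_path) as fh:
            return cls(aln, fh.read(), rate_classes)

    def _spectra(self, theta, omega_of_branch):
        cache: dict[float, tuple] = {}
        out = {}
        for b in self.engine.branches:
            om = omega_of_branch[b.label]
            if om not in cache:
                Q, total, _syn = codon_generator(theta, om, self.pi_nt, self.spec)
                cache[om] = spectral(Q / total, self.pi)
            out[b.label] = cache[om]
        return out

    def _loglik(self, theta, t_of, omega_of) -> float:
        spectra = self._spectra(theta, omega_of)
        P = {b: transition_matrix(*spectra[b], t_of[b]) for b in t_of}
        return self.engine.loglik(P, self.pi)

    def fit(self, max_sweeps: int = 25, tol: float = 1e-6, verbose: bool = False) -> CodonResults:
        eng = self.engine
        t_of = {b.label: (b.length if b.length else 0.1) for b in eng.branches}
        omega_of = {b.label: 0.5 for b in eng.branches}
        theta = np.ones(self.spec.free_count)

        ll = self._loglik(theta, t_of, omega_of)
        sweeps = 0
        converged = False
        for sweep in range(max_sweeps):
            sweeps = sweep + 1
            # per-branch (t, omega)
            for b in eng.branches:
                spectra = self._spectra(theta, omega_of)
                P = {lbl: transition_matrix(*spectra[lbl], t_of[lbl]) for lbl in t_of}
                F, G, logsc = eng.edge_vectors(b.label, P, self.pi)

                def opt_t_given_omega(om: float) -> tuple[float, float]:
                    Q, total, _ = codon_generator(theta, om, self.pi_nt, self.spec)
                    lam, U, V = spectral(Q / total, self.pi)
                    coeff = (F @ U) * (G @ V.T)

                    def neg(t):
                        lk = coeff @ np.exp(lam * t)
                        return -float(eng.counts @ (np.log(np.maximum(lk, 1e-300)) + logsc))

                    res = optimize.minimize_scalar(neg, bounds=(0.0, self.T_MAX), method="bounded",
                                                   options={"xatol": 1e-8})
                    return float(res.x), -float(res.fun)

                def neg_omega(log_om):
                    _, val = opt_t_given_omega(float(np.exp(log_om)))
                    return -val

                res_om = optimize.minimize_scalar(
                    neg_omega, bounds=(np.log(1e-4), np.log(self.OMEGA_MAX)), method="bounded",
                    options={"xatol": 1e-4},
                )
                om = float(np.exp(res_om.x))
                tval, _ = opt_t_given_omega(om)
                omega_of[b.label] = om
                t_of[b.label] = tval

            # global exchangeabilities (first class fixed at 1)
            if self.spec.free_count > 1:
                x0 = np.log(theta[1:])

                def neg_theta(x):
                    th = np.concatenate([[1.0], np.exp(x)])
                    return -self._loglik(th, t_of, omega_of)

                res = optimize.minimize(neg_theta, x0, method="Nelder-Mead",
                                        options={"maxfev": 40 + 20 * len(x0), "xatol": 1e-4, "fatol": 1e-6})
                theta = np.concatenate([[1.0], np.exp(res.x)])

            new_ll = self._loglik(theta, t_of, omega_of)
            if verbose:
                print(f"sweep {sweeps}: loglik {new_ll:.6f}")
            if abs(new_ll - ll) < tol:
                ll = new_ll
                converged = True
                break
            ll = new_ll

        ds = {
            lbl: ds_from_t(t_of[lbl], theta, omega_of[lbl], self.pi_nt, self.spec)
            for lbl in t_of
        }
        return CodonResults(
            model=self,
            loglik=ll,
            theta=theta,
            branch_t=t_of,
            branch_omega=omega_of,
            branch_ds=ds,
            pi_nt=self.pi_nt,
            n_iter=sweeps,
            converged=converged,
        )


class NucleotideModel:
    """GTR(+Gamma)(+I) nucleotide model on a fixed topology."""

    T_MAX = 30.0

    def __init__(
        self,
        alignment: Alignment,
        tree: str | Node,
        rate_classes: str | RateClassSpec = "012345",
        gamma_categories: int = 4,
        invariant: bool = True,
        frequencies: str = "empirical",
    ):
        self.alignment = alignment
        self.spec = rate_classes if isinstance(rate_classes, RateClassSpec) else parse_rate_class(rate_classes)
        root = parse_newick(tree) if isinstance(tree, str) else tree
        if set(root.leaf_names()) != set(alignment.taxa):
            raise ValueError("tree tips and alignment taxa differ")
        taxa_order = root.copy().leaf_names()
        patterns, counts = _nt_patterns(alignment, taxa_order)
        self.engine = _Engine(root, patterns, counts, 4, taxa_order)
        self.gamma_categories = gamma_categories if gamma_categories and gamma_categories > 1 else 0
        self.invariant = invariant
        if frequencies == "equal":
            self.pi = np.full(4, 0.25)
        else:
            counts4 = np.ones(4)
            for row in alignment.rows:
                for b in row:
                    if b in NT_INDEX:
                        counts4[NT_INDEX[b]] += 1
            self.pi = counts4 / counts4.sum()
        # per-pattern invariant-site partial: pi of the shared state, or 0
        pats = patterns
        npat = pats.shape[1]
        inv = np.zeros(npat)
        for p in range(npat):
            col = pats[:, p]
            obs = col[col >= 0]
            if obs.size == 0:
                inv[p] = 1.0
            elif np.all(obs == obs[0]):
                inv[p] = self.pi[obs[0]]
        self._pinv_partial = inv

    def _rates(self, alpha: float | None) -> np.ndarray:
        k = self.gamma_categories
        if not k or alpha is None:
            return np.array([1.0])
        qs = stats.gamma.ppf((2 * np.arange(k) + 1) / (2 * k), a=alpha, scale=1.0 / alpha)
        return qs / qs.mean()

    def _loglik(self, theta, alpha, p_inv, t_of) -> float:
        Q = gtr_generator(theta, self.pi, self.spec)
        lam, U, V = spectral(Q, self.pi)
        rates = self._rates(alpha)
        k = len(rates)
        w = [(1.0 - p_inv) / k] * k
        P = {
            lbl: [transition_matrix(lam, U, V, r * t) for r in rates]
            for lbl, t in t_of.items()
        }
        return self.engine.loglik(P, self.pi, weights=w, pinv=p_inv, pinv_partial=self._pinv_partial)

    def fit(self, max_sweeps: int = 25, tol: float = 1e-6, verbose: bool = False) -> NucleotideResults:
        eng = self.engine
        t_of = {b.label: (b.length if b.length else 0.1) for b in eng.branches}
        theta = np.ones(self.spec.free_count)
        alpha: float | None = 1.0 if self.gamma_categories else None
        p_inv = 0.1 if self.invariant else 0.0

        ll = self._loglik(theta, alpha, p_inv, t_of)
        sweeps = 0
        converged = False
        for sweep in range(max_sweeps):
            sweeps = sweep + 1
            Q = gtr_generator(theta, self.pi, self.spec)
            lam, U, V = spectral(Q, self.pi)
            rates = self._rates(alpha)
            k = len(rates)
            w = [(1.0 - p_inv) / k] * k
            for b in eng.branches:
                P = {
                    lbl: [transition_matrix(lam, U, V, r * t) for r in rates]
                    for lbl, t in t_of.items()
                }
                # category-wise edge vectors; combine with invariant term
                coeffs = []
                for c in range(k):
                    Pc = {lbl: P[lbl][c] for lbl in P}
                    F, G, logsc = eng.edge_vectors(b.label, Pc, self.pi)
                    coeffs.append(((F @ U) * (G @ V.T), logsc))

                def neg_t(t):
                    m = None
                    parts = []
                    for c in range(k):
                        coeff, logsc = coeffs[c]
                        lk = coeff @ np.exp(lam * rates[c] * t)
                        parts.append((np.log(np.maximum(lk, 1e-300)) + logsc, w[c]))
                    logs = np.stack([p[0] + np.log(p[1]) for p in parts])
                    mx = logs.max(axis=0)
                    var = np.exp(logs - mx).sum(axis=0)
                    log_l = mx + np.log(var)
                    if p_inv > 0:
                        with np.errstate(divide="ignore"):
                            log_inv = np.where(
                                self._pinv_partial > 0,
                                np.log(p_inv) + np.log(np.maximum(self._pinv_partial, 1e-300)),
                                -np.inf,
                            )
                        mm = np.maximum(log_l, log_inv)
                        log_l = mm + np.log(
                            np.exp(log_l - mm) + np.where(np.isfinite(log_inv), np.exp(log_inv - mm), 0.0)
                        )
                    return -float(eng.counts @ log_l)

                res = optimize.minimize_scalar(neg_t, bounds=(0.0, self.T_MAX), method="bounded",
                                               options={"xatol": 1e-8})
                t_of[b.label] = float(res.x)

            # globals
            free = []
            if self.spec.free_count > 1:
                free.append(("theta", self.spec.free_count - 1))
            if self.gamma_categories:
                free.append(("alpha", 1))
            if self.invariant:
                free.append(("pinv", 1))
            if free:
                x0 = []
                if self.spec.free_count > 1:
                    x0.extend(np.log(theta[1:]))
                if self.gamma_categories:
                    x0.append(np.log(alpha))
                if self.invariant:
                    p0 = min(max(p_inv, 1e-4), 0.95)
                    x0.append(np.log(p0 / (1 - p0)))

                def unpack(x):
                    i = 0
                    th = theta
                    al = alpha
                    pv = p_inv
                    if self.spec.free_count > 1:
                        th = np.concatenate([[1.0], np.exp(x[i : i + self.spec.free_count - 1])])
                        i += self.spec.free_count - 1
                    if self.gamma_categories:
                        al = float(np.exp(np.clip(x[i], -4, 6)))
                        i += 1
                    if self.invariant:
                        pv = float(1 / (1 + np.exp(-x[i])))
                        pv = min(pv, 0.99)
                        i += 1
                    return th, al, pv

                def neg_global(x):
                    th, al, pv = unpack(np.asarray(x))
                    return -self._loglik(th, al, pv, t_of)

                res = optimize.minimize(neg_global, np.asarray(x0), method="Nelder-Mead",
                                        options={"maxfev": 40 + 20 * len(x0), "xatol": 1e-4, "fatol": 1e-6})
                theta, alpha, p_inv = unpack(res.x)

            new_ll = self._loglik(theta, alpha, p_inv, t_of)
            if verbose:
                print(f"sweep {sweeps}: loglik {new_ll:.6f}")
            if abs(new_ll - ll) < tol:
                ll = new_ll
                converged = True
                break
            ll = new_ll

        return NucleotideResults(
            model=self,
            loglik=ll,
            theta=theta,
            alpha=alpha,
            p_inv=p_inv,
            branch_t=t_of,
            pi=self.pi,
            n_iter=sweeps,
            converged=converged,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers


def estimate_branch_lengths_codon(aln: Alignment, topology: str | Node, spec: str | RateClassSpec) -> RateTree:
    """ML per-branch synonymous divergence (dS) under the MG94 model."""
    return CodonModel(aln, topology, spec).fit().rate_tree()


def estimate_branch_lengths_nt(
    aln: Alignment, topology: str | Node, gamma_categories: int = 4, invariant: bool = True
) -> RateTree:
    """ML per-branch total divergence (d) under GTR+Gamma+I."""
    return NucleotideModel(
        aln, topology, gamma_categories=gamma_categories, invariant=invariant
    ).fit().rate_tree()
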