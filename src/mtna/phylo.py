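"""Neighbor-joining trees with bootstrap support and an admixture test.

The question answered here: do focal haplotypes (e.g. African lines
carrying a derived indel allele) cluster with a differentiated source
population (e.g. European lines) rather than with their own population —
the tree signature of recent admixture?

Distances are p-distances with pairwise deletion of gaps/ambiguous sites
(Jukes–Cantor correction optional), trees are built with the Saitou–Nei
neighbor-joining algorithm using the Studier–Keppler Q criterion, and
internal-edge support comes from bootstrap resampling of alignment columns.
Trees are Bio.Phylo objects, so Newick serialization round-trips.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree
from scipy.spatial.distance import squareform

from .genotyping import encode_seq


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A,C,G,T,-,N}.

    Sequences are stored as uint8 codes (A,C,G,T -> 0..3; gaps, N and any
    other symbol -> 4 and are excluded from distances pairwise).
    """

    names: list[str]
    codes: np.ndarray  # (n_taxa, n_columns) uint8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise ValueError("codes must be (n_taxa, n_columns)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        names, seqs = zip(*records)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must all have the same length")
        return cls(list(names), np.vstack([encode_seq(s) for s in seqs]))

    def to_records(self) -> list[tuple[str, str]]:
        lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
        return [
            (nm, bytes(lut[np.minimum(self.codes[i], 4)]).decode())
            for i, nm in enumerate(self.names)
        ]


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def _pair_site_matrices(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair, per-column difference and comparability indicator matrices."""
    codes = aln.codes
    valid = codes < 4
    ii, jj = _pair_indices(aln.n_taxa)
    comp = (valid[ii] & valid[jj]).astype(np.float32)
    diff = ((codes[ii] != codes[jj]).astype(np.float32)) * comp
    return diff, comp


def _jukes_cantor(p: np.ndarray) -> np.ndarray:
    arg = 1.0 - 4.0 * p / 3.0
    if np.any(arg <= 0):
        raise ValueError("p-distance too large for the Jukes-Cantor correction")
    return -0.75 * np.log(arg)


def p_distance(
    aln: Alignment,
    model: str = "p",
    complete_deletion: bool = False,
) -> np.ndarray:
    """Pairwise distance matrix with pairwise (default) or complete deletion.

    p-distance = differing sites / comparable sites, where a site is
    comparable for a pair when both sequences carry an unambiguous
    nucleotide. ``model="jc"`` applies the Jukes–Cantor correction.
    """
    if model not in ("p", "jc"):
        raise ValueError("model must be 'p' or 'jc'")
    work = aln
    if complete_deletion:
        keep = (aln.codes < 4).all(axis=0)
        work = Alignment(aln.names, aln.codes[:, keep])
    diff, comp = _pair_site_matrices(work)
    comps = comp.sum(axis=1)
    if np.any(comps == 0):
        raise ValueError("a sequence pair shares no comparable columns")
    p = diff.sum(axis=1) / comps
    if model == "jc":
        p = _jukes_cantor(p)
    return squareform(p.astype(float))


def _nj_core(dist: np.ndarray) -> tuple[list, tuple]:
    """Saitou–Nei agglomeration; returns merge records and the final join.

    Node ids: 0..n-1 are the input taxa; each merge creates the next id.
    ``merges`` is a list of (id_a, id_b, len_a, len_b, new_id); ``final``
    is (ids, lengths) of the terminal 3- (or 2-) way join forming the
    unrooted tree's central node.
    """
    n = dist.shape[0]
    if dist.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix for >= 2 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dist
    active = list(range(n))
    next_id = n
    merges = []
    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        k = int(np.argmin(Q))  # first minimum = smallest (i, j) pair
        i_, j_ = divmod(k, m)
        if i_ > j_:
            i_, j_ = j_, i_
        d_ij = sub[i_, j_]
        li = d_ij / 2 + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = d_ij - li
        if li < 0:  # clamp, moving the deficit to the sister branch
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        new_to_rest = (sub[i_, :] + sub[j_, :] - d_ij) / 2
        a, b = active[i_], active[j_]
        remaining = [x for x in active if x not in (a, b)]
        for pos, other in enumerate(active):
            if other in (a, b):
                continue
            D[next_id, other] = D[other, next_id] = new_to_rest[pos]
        merges.append((a, b, float(li), float(lj), next_id))
        active = remaining + [next_id]
        next_id += 1
    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = D[a, b], D[a, c], D[b, c]
        la = max((dab + dac - dbc) / 2, 0.0)
        lb = max((dab + dbc - dac) / 2, 0.0)
        lc = max((dac + dbc - dab) / 2, 0.0)
        final = ((a, b, c), (la, lb, lc))
    else:  # two nodes left
        a, b = active
        half = max(D[a, b] / 2, 0.0)
        final = ((a, b), (half, half))
    return merges, final


def neighbor_joining(dist: np.ndarray, names: Sequence[str]) -> Tree:
    """Unrooted neighbor-joining tree (Bio.Phylo) from a distance matrix.

    Deterministic: ties in the Q criterion resolve to the smallest index
    pair, negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch.
    """
    dist = np.asarray(dist, dtype=float)
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    merges, final = _nj_core(dist)
    nodes: dict[int, Clade] = {
        i: Clade(name=str(nm)) for i, nm in enumerate(names)
    }
    for a, b, la, lb, new in merges:
        nodes[a].branch_length = la
        nodes[b].branch_length = lb
        nodes[new] = Clade(clades=[nodes[a], nodes[b]])
    ids, lens = final
    for node_id, bl in zip(ids, lens):
        nodes[node_id].branch_length = bl
    root = Clade(clades=[nodes[i] for i in ids])
    return Tree(root=root, rooted=False)


def _merge_leafsets(n: int, merges: list) -> list[frozenset]:
    """Leaf-index sets below every internal edge created by merges."""
    leafsets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for a, b, _, _, new in merges:
        s = leafsets[a] | leafsets[b]
        leafsets[new] = s
        out.append(s)
    return out


def _canonical(s: frozenset, n: int) -> frozenset:
    """Orientation-free bipartition key: the side not containing taxon 0."""
    if 0 in s:
        return frozenset(range(n)) - s
    return s


def _tree_bipartition_counts(n: int, merges: list) -> set[frozenset]:
    out = set()
    for s in _merge_leafsets(n, merges):
        if 1 < len(s) < n - 1:
            out.add(_canonical(s, n))
    return out


def bootstrap_support(
    aln: Alignment,
    tree: Tree | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
    complete_deletion: bool = False,
) -> Tree:
    """Attach bootstrap supports (0–100) to a tree's internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times, a
    neighbor-joining tree is rebuilt per replicate, and each internal
    bipartition's occurrence frequency is mapped onto the given tree (the
    full-data NJ tree if none is supplied). Bipartitions are matched by
    leaf set, independent of rooting.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    work = aln
    if complete_deletion:
        keep = (aln.codes < 4).all(axis=0)
        work = Alignment(aln.names, aln.codes[:, keep])
    n = work.n_taxa
    L = work.n_columns
    if tree is None:
        tree = neighbor_joining(p_distance(work, model=model), work.names)
    else:
        tree = copy.deepcopy(tree)

    diff, comp = _pair_site_matrices(work)
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=n_reps)
    W = weights.astype(np.float32).T  # (L, n_reps)
    diffs = diff @ W  # (n_pairs, n_reps)
    comps = comp @ W
    if np.any(comps == 0):
        raise ValueError("a bootstrap replicate left a pair with no data")
    P = diffs / comps
    if model == "jc":
        P = _jukes_cantor(P)

    counts: dict[frozenset, int] = {}
    for rep in range(n_reps):
        d = squareform(P[:, rep].astype(float))
        merges, _ = _nj_core(d)
        for bip in _tree_bipartition_counts(n, merges):
            counts[bip] = counts.get(bip, 0) + 1

    index = {nm: i for i, nm in enumerate(work.names)}
    all_leaves = frozenset(range(n))
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        s = frozenset(index[t.name] for t in clade.get_terminals())
        if 1 < len(s) < n - 1:
            clade.confidence = 100.0 * counts.get(_canonical(s, n), 0) / n_reps
    return tree


def root_with_outgroup(tree: Tree, outgroup: Sequence[str]) -> Tree:
    """Root a copy of the tree on the edge separating the outgroup taxa.

    Warns (and roots at the outgroups' common ancestor) when the outgroup
    is not monophyletic in the unrooted topology.
    """
    rooted = copy.deepcopy(tree)
    outgroup = list(outgroup)
    missing = set(outgroup) - {t.name for t in rooted.get_terminals()}
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    ingroup_leaf = next(
        t.name for t in rooted.get_terminals() if t.name not in outgroup
    )
    rooted.root_with_outgroup(ingroup_leaf)  # orient: outgroup MRCA is a clade
    mrca = rooted.common_ancestor(outgroup)
    under = {t.name for t in mrca.get_terminals()}
    if under != set(outgroup):
        warnings.warn(
            "outgroup is not monophyletic; rooting on the edge that best "
            "separates it",
            stacklevel=2,
        )
    half = (mrca.branch_length or 0.0) / 2
    rooted.root_with_outgroup(*outgroup, outgroup_branch_length=half)
    rooted.rooted = True
    return rooted


@dataclass(frozen=True)
class AdmixtureVerdict:
    admixed: bool
    support: float | None
    clade_taxa: tuple[str, ...]


def clade_support(tree: Tree, taxa: Sequence[str]) -> tuple[float | None, tuple[str, ...]]:
    """Support of the smallest clade containing all the given taxa."""
    mrca = tree.common_ancestor(list(taxa))
    members = tuple(sorted(t.name for t in mrca.get_terminals()))
    return mrca.confidence, members


def is_admixed(
    tree: Tree,
    focal: Sequence[str],
    source: Sequence[str],
) -> AdmixtureVerdict:
    """Do the focal taxa cluster inside the source population?

    True iff some internal edge has an ingroup side containing every focal
    taxon plus at least one (possibly all) source-population taxa and
    nothing else — i.e. the focal haplotypes join the source clade rather
    than their own population. Reports the best-supported such edge.
    """
    focal_set = frozenset(focal)
    source_set = frozenset(source)
    if focal_set & source_set:
        raise ValueError("focal and source taxa must be disjoint")
    all_names = frozenset(t.name for t in tree.get_terminals())
    missing = (focal_set | source_set) - all_names
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    best: tuple[float, frozenset] | None = None
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        for s in (side, all_names - side):
            if not (1 < len(s) < len(all_names)):
                continue
            if focal_set <= s <= (focal_set | source_set) and s & source_set:
                conf = clade.confidence if clade.confidence is not None else -1.0
                if best is None or conf > best[0]:
                    best = (conf, s)
    if best is None:
        return AdmixtureVerdict(False, None, ())
    conf, s = best
    return AdmixtureVerdict(True, None if conf < 0 else conf, tuple(sorted(s)))


__all__ = [
    "Alignment",
    "AdmixtureVerdict",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "clade_support",
    "is_admixed",
]
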