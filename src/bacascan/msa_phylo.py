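"""Profile-guided alignment, distances, neighbor-joining and clades.

Candidate proteins are aligned to the mining profile via their Viterbi
paths (match-column alignment: insert-state residues dropped, deletes as
gaps), unreliable columns removed by a gap-fraction rule, Poisson-corrected
distances computed, and a neighbor-joining tree inferred, rooted on the
outgroup families (ExsE and the Bradyrhizobium homologous clade), and
partitioned into the three primary clades:

* Clade A — the outgroup clade,
* Clade C — the smallest clade containing the largest SSN component plus
  the component enriched for the SbmA/BacA label,
* Clade B — the remaining ingroup leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import ProteinRecord
from .profile_hmm import ProfileHMM, viterbi_path

GAP = "-"
P_CAP = 0.95  # keeps -ln(1-p) finite for saturated pairs


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("ragged alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_gap_fraction(self) -> np.ndarray:
        n = len(self.rows)
        return np.array(
            [sum(1 for r in self.rows if r[c] == GAP) / n for c in range(self.width)]
        )


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.d)).max() > 1e-12 if n else False:
            raise ValueError("diagonal must be zero")


@dataclass
class CladeAssignment:
    clade: dict[str, str]  # protein_id -> A / B / C / unassigned
    long_branch: dict[str, bool]


def align_to_profile(hmm: ProfileHMM, proteins: Sequence[ProteinRecord]) -> MSA:
    """Match-column alignment of each protein via its Viterbi path.

    Residues assigned to insert states are dropped; delete states emit a
    gap; match columns outside the local alignment are gaps.  Width equals
    the number of match states.
    """
    if not proteins:
        raise ValueError("no proteins to align")
    K = hmm.n_match
    ids, rows = [], []
    for rec in proteins:
        _, path = viterbi_path(hmm, rec.sequence)
        row = [GAP] * K
        placed = 0
        for state, k, i in path:
            if state == "M":
                row[k - 1] = rec.sequence[i]
                placed += 1
        if placed == 0:
            warnings.warn(f"empty profile alignment for {rec.protein_id}", stacklevel=2)
        ids.append(rec.protein_id)
        rows.append("".join(row))
    return MSA(ids, rows)


def trim_columns(msa: MSA, max_gap_fraction: float = 0.5) -> MSA:
    """Keep exactly the columns with gap fraction <= max_gap_fraction."""
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    gf = msa.column_gap_fraction()
    keep = [c for c in range(msa.width) if gf[c] <= max_gap_fraction]
    if not keep:
        raise ValueError("no columns survive trimming")
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    return MSA(list(msa.ids), rows)


def distance_matrix(msa: MSA) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p), p capped at 0.95.

    p is the mismatch fraction over columns where both rows are non-gap;
    pairs sharing no columns get the current maximum distance + 1.
    """
    n = len(msa.ids)
    enc = np.array([[ord(c) for c in row] for row in msa.rows], dtype=np.int32)
    gap = ord(GAP)
    d = np.zeros((n, n))
    no_overlap = []
    for i in range(n):
        both = (enc[i] != gap)[None, :] & (enc[i + 1 :] != gap)
        shared = both.sum(axis=1)
        mism = ((enc[i][None, :] != enc[i + 1 :]) & both).sum(axis=1)
        for off, (s, m) in enumerate(zip(shared, mism)):
            j = i + 1 + off
            if s == 0:
                no_overlap.append((i, j))
                continue
            p = min(m / s, P_CAP)
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    if no_overlap:
        warnings.warn(f"{len(no_overlap)} pairs share no alignment columns", stacklevel=2)
        fill = d.max() + 1.0
        for i, j in no_overlap:
            d[i, j] = d[j, i] = fill
    return DistanceMatrix(list(msa.ids), d)


def _new_leaf(taxon_ns: dendropy.TaxonNamespace, label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = taxon_ns.require_taxon(label=label)
    return node


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining (Q criterion) as an unrooted tree.

    Ties in Q are broken by the first (row-major) minimum; negative branch
    lengths are clamped to zero with the deficit moved to the sister
    branch, so the pair's summed length is preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = [_new_leaf(tns, pid) for pid in dm.ids]
    D = dm.d.astype(float).copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        idx = int(np.argmin(Q))
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    # final three-way join at an unrooted central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = dendropy.Node()
    for node, ln in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _leafset_below(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= below[ch]
            below[node] = frozenset(s)
    return below


def root_tree(tree: dendropy.Tree, outgroup_ids: set[str]) -> dendropy.Tree:
    """Root on the branch subtending the smallest clade holding the outgroup.

    If only the whole tree contains every outgroup id, the tree is returned
    rooted at the outgroup MRCA (the existing seed node) with a warning.
    """
    if not outgroup_ids:
        raise ValueError("empty outgroup set")
    t = tree.clone(depth=1)
    labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    missing = outgroup_ids - labels
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    below = _leafset_below(t)
    total = below[t.seed_node]
    best_node = None
    best_size = len(total) + 1
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        side = below[node]
        if outgroup_ids <= side:
            size = len(side)
        elif not (outgroup_ids & side):
            size = len(total) - len(side)
        else:
            continue
        if size < best_size:
            best_size = size
            best_node = node
    if best_node is None or best_size == len(total):
        warnings.warn("outgroup spans the whole tree; rooting unchanged", stacklevel=2)
        t.is_rooted = True
        return t
    edge = best_node.edge
    half = (edge.length or 0.0) / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half)
    t.is_rooted = True
    return t


def assign_clades(
    tree: dendropy.Tree,
    components: Sequence[Sequence[str]],
    hmm_labels: Mapping[str, str],
    outgroup_labels: tuple[str, ...] = ("ExsE", "Brady"),
    bacA_label: str = "BacA",
) -> CladeAssignment:
    """Partition the leaves of a rooted tree into clades A, B and C."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    clade = {pid: "unassigned" for pid in leaves}
    out_ids = {pid for pid in leaves if hmm_labels.get(pid) in outgroup_labels}
    if not out_ids:
        warnings.warn("no outgroup-labeled proteins; clades unassigned", stacklevel=2)
        return CladeAssignment(clade, {pid: False for pid in leaves})
    below = _leafset_below(tree)
    children = tree.seed_node.child_nodes()
    out_child = max(children, key=lambda ch: len(out_ids & below[ch]) / max(len(below[ch]), 1))
    clade_a = set(below[out_child])
    for pid in clade_a:
        clade[pid] = "A"
    ingroup = set(leaves) - clade_a

    comp_lists = [list(c) for c in components if c]
    bacA_comp = None
    best_frac = 0.0
    for c in comp_lists:
        frac = sum(1 for pid in c if hmm_labels.get(pid) == bacA_label) / len(c)
        if frac > best_frac or (frac == best_frac > 0 and bacA_comp is not None and len(c) > len(bacA_comp)):
            best_frac = frac
            bacA_comp = c
    if not comp_lists or bacA_comp is None or best_frac == 0.0:
        warnings.warn("seed components absent; ingroup left unassigned", stacklevel=2)
        return CladeAssignment(clade, {pid: False for pid in leaves})
    # the "core" anchor component: largest cluster whose majority label is
    # neither an outgroup family nor the BacA cluster itself (the BacA
    # cluster being largest is a degenerate case the MRCA rule must survive)
    def majority(c: Sequence[str]) -> str:
        labs = [hmm_labels.get(pid, "other") for pid in c]
        return max(set(labs), key=lambda lab: (labs.count(lab), lab))

    core_candidates = [
        c
        for c in comp_lists
        if set(c) != set(bacA_comp) and majority(c) not in outgroup_labels
    ]
    pool = core_candidates if core_candidates else comp_lists
    largest = max(pool, key=lambda c: (len(c), c[0]))
    target = (set(largest) | set(bacA_comp)) & ingroup
    if not target:
        warnings.warn("seed components fall outside the ingroup; unassigned", stacklevel=2)
        return CladeAssignment(clade, {pid: False for pid in leaves})
    mrca_leaves: frozenset[str] | None = None
    for node in tree.postorder_node_iter():
        under = below[node]
        if target <= under and (mrca_leaves is None or len(under) < len(mrca_leaves)):
            mrca_leaves = under
    clade_c = set(mrca_leaves or ()) - clade_a
    for pid in clade_c:
        clade[pid] = "C"
    for pid in ingroup - clade_c:
        clade[pid] = "B"
    return CladeAssignment(clade, {pid: False for pid in leaves})


def flag_long_branches(tree: dendropy.Tree, c: float = 5.0) -> dict[str, bool]:
    """Flag leaves whose terminal branch exceeds c x median terminal branch."""
    if c <= 0:
        raise ValueError("multiplier must be positive")
    terms = {lf.taxon.label: (lf.edge.length or 0.0) for lf in tree.leaf_node_iter()}
    med = float(np.median(list(terms.values()))) if terms else 0.0
    return {pid: (ln > c * med if med > 0 else False) for pid, ln in terms.items()}


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits (smaller-side leaf sets canonicalized)."""
    t = tree.clone(depth=1)
    below = _leafset_below(t)
    total = below[t.seed_node]
    splits: set[frozenset[str]] = set()
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        side = below[node]
        if len(side) < 2 or len(side) > len(total) - 2:
            continue
        other = frozenset(total - side)
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits
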