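"""Sequence similarity network construction.

All-vs-all gapped local alignment (Smith-Waterman, affine gaps, BLOSUM62)
with Karlin-Altschul statistics.  Each pair's raw score is converted to a
bit score, to an E-value for query length m against target length n, and
finally to the EFI-EST-style alignment score AS = -log10(E); edges with
AS above a threshold (115 in the study this pipeline reproduces,
corresponding to roughly >= 35% identity) form the network, and clusters
are its connected components.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .io_formats import ALPHABET, ProteinRecord, encode_sequence

LN2 = math.log(2.0)
LOG10_2 = math.log10(2.0)


def _blosum62_matrix() -> np.ndarray:
    """21x21 BLOSUM62 over AMINO_ACIDS + X, with X scoring 0 vs everything."""
    from Bio.Align import substitution_matrices

    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(ALPHABET[:20]):
        for j, c in enumerate(ALPHABET[:20]):
            m[i, j] = int(b[a, c])
    # X row/column: 0 against everything (parse-time normalization contract)
    m[20, :] = 0
    m[:, 20] = 0
    return m


@dataclass
class ScoringScheme:
    """BLOSUM62/11/1 with standard gapped Karlin-Altschul parameters."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lambda_ka: float = 0.267  # nats per raw-score unit
    k_ka: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("need gap_open >= gap_extend > 0")
        if self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")


@dataclass
class PairAlignment:
    id1: str
    id2: str
    raw_score: int
    bit_score: float
    e_value: float
    alignment_score: float
    pct_identity: float
    aligned_columns: int


@njit(cache=True)
def _sw_kernel(a, b, S, go, ge):
    """Affine-gap Smith-Waterman with traceback.

    Gap of length k costs go + (k-1)*ge.  Traceback ties prefer
    diagonal > up (gap in b) > left (gap in a).  Returns
    (raw, identities, aligned_columns).
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -1000000, dtype=np.int32)
    F = np.full((n + 1, m + 1), -1000000, dtype=np.int32)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open from H, 1 extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e1 = H[i, j - 1] - go
            e2 = E[i, j - 1] - ge
            if e1 >= e2:
                E[i, j] = e1
                ptr_e[i, j] = 0
            else:
                E[i, j] = e2
                ptr_e[i, j] = 1
            f1 = H[i - 1, j] - go
            f2 = F[i - 1, j] - ge
            if f1 >= f2:
                F[i, j] = f1
                ptr_f[i, j] = 0
            else:
                F[i, j] = f2
                ptr_f[i, j] = 1
            d = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            # preference on ties: diag > up > left > stop
            h = 0
            p = 0
            if E[i, j] >= h:
                h = E[i, j]
                p = 3
            if F[i, j] >= h:
                h = F[i, j]
                p = 2
            if d >= h:
                h = d
                p = 1
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from the first-reached best cell
    ident = 0
    cols = 0
    i = bi
    j = bj
    state = 0  # 0 H, 1 F(up), 2 E(left)
    while best > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    ident += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            nxt = ptr_f[i, j]
            i -= 1
            state = 1 if nxt == 1 else 0
        else:
            cols += 1
            nxt = ptr_e[i, j]
            j -= 1
            state = 2 if nxt == 1 else 0
    return best, ident, cols


def bit_score(raw: float, scheme: ScoringScheme) -> float:
    """Karlin-Altschul conversion: bits = (lambda*raw - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be >= 0")
    return (scheme.lambda_ka * raw - math.log(scheme.k_ka)) / LN2


def alignment_score(bits: float, m: int, n: int) -> float:
    """EFI-EST-style score: AS = -log10(m * n * 2**-bits)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return bits * LOG10_2 - math.log10(m * n)


def local_align(a: str | ProteinRecord, b: str | ProteinRecord, scheme: ScoringScheme | None = None) -> PairAlignment:
    """Optimal gapped local alignment of two sequences with KA statistics."""
    if scheme is None:
        scheme = ScoringScheme()
    id1, s1 = (a.protein_id, a.sequence) if isinstance(a, ProteinRecord) else ("seq1", a)
    id2, s2 = (b.protein_id, b.sequence) if isinstance(b, ProteinRecord) else ("seq2", b)
    if not s1 or not s2:
        raise ValueError("cannot align empty sequences")
    e1 = encode_sequence(s1)
    e2 = encode_sequence(s2)
    raw, ident, cols = _sw_kernel(e1, e2, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    bits = bit_score(raw, scheme)
    a_s = alignment_score(bits, len(s1), len(s2))
    ev = 10.0 ** (-a_s) if a_s < 300 else 0.0
    pct = 100.0 * ident / cols if cols else 0.0
    return PairAlignment(id1, id2, int(raw), bits, ev, a_s, pct, int(cols))


def candidate_pairs(
    proteins: list[ProteinRecord],
    prefilter_kmer: int | None = None,
) -> list[tuple[int, int]]:
    """Unordered index pairs to align; optional shared-k-mer prefilter.

    The prefilter is lossless for pairs sharing at least one exact word of
    the configured size (such pairs are always retained).
    """
    n = len(proteins)
    if prefilter_kmer is None:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    k = prefilter_kmer
    kmer_sets = []
    for rec in proteins:
        s = rec.sequence
        kmer_sets.append({s[i : i + k] for i in range(len(s) - k + 1)})
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if kmer_sets[i] & kmer_sets[j]:
                pairs.append((i, j))
    return pairs


def all_vs_all(
    proteins: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    prefilter_kmer: int | None = None,
) -> list[PairAlignment]:
    """One PairAlignment per surviving unordered pair of proteins."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    if scheme is None:
        scheme = ScoringScheme()
    out = []
    for i, j in candidate_pairs(proteins, prefilter_kmer):
        out.append(local_align(proteins[i], proteins[j], scheme))
    return out


@dataclass
class SSN:
    """Thresholded similarity network with stable component ids.

    Components are numbered by decreasing size, ties by the
    lexicographically smallest member.
    """

    nodes: list[str]
    edges: list[PairAlignment]
    threshold: float
    components: list[list[str]]
    component_of: dict[str, int]
    graph: nx.Graph


def build_network(
    pairs: list[PairAlignment],
    threshold: float,
    nodes: list[str] | None = None,
) -> SSN:
    """Keep pairs with alignment_score >= threshold; compute components.

    ``nodes`` lists the full protein universe so edge-free proteins appear
    as singletons; by default it is the union of pair endpoints.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    g = nx.Graph()
    if nodes is None:
        node_list: list[str] = []
        seen = set()
        for p in pairs:
            for pid in (p.id1, p.id2):
                if pid not in seen:
                    seen.add(pid)
                    node_list.append(pid)
        nodes = node_list
    g.add_nodes_from(nodes)
    edges = [p for p in pairs if p.alignment_score >= threshold and p.id1 != p.id2]
    for p in edges:
        g.add_edge(p.id1, p.id2, alignment_score=p.alignment_score, pct_identity=p.pct_identity)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    comp_of = {pid: i for i, c in enumerate(comps) for pid in c}
    return SSN(list(nodes), edges, threshold, comps, comp_of, g)


@dataclass
class ComponentStats:
    component_id: int
    size: int
    median_pct_identity: float  # NaN for edge-free components
    members: list[str]


def component_stats(ssn: SSN) -> list[ComponentStats]:
    """Per-component size, median internal-edge identity and members."""
    out = []
    for cid, members in enumerate(ssn.components):
        mset = set(members)
        idents = [e.pct_identity for e in ssn.edges if e.id1 in mset and e.id2 in mset]
        med = statistics.median(idents) if idents else float("nan")
        out.append(ComponentStats(cid, len(members), med, list(members)))
    assert sum(c.size for c in out) == len(ssn.nodes)
    return out
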