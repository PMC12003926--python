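"""Profile hidden Markov models for protein-family mining and annotation.

A family profile is built from a seed alignment (match columns chosen by
a residue-occupancy rule, emissions and transitions pseudocounted), and
candidate proteins are scored in a local (Smith-Waterman-style) alignment
mode: the alignment may enter the model at any match state (uniform entry
probability 1/K), leave after any match state at no cost, and flanking
residues are emitted by the background at zero log-odds cost.  Scores are
log2 P(seq|model) / P(seq|background) in bits; Viterbi takes the single
best state path and forward sums over all of them, so forward >= Viterbi
always.  E-values come from a Gumbel fit to forward scores of random
background sequences, in place of HMMER's internal calibration.

This is deliberately a single-hit local model: no multi-hit mode, no
biased-composition filters and no domain envelopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .io_formats import (
    BACKGROUND,
    AA_INDEX,
    X_INDEX,
    ProteinRecord,
    SeedAlignment,
    encode_sequence,
    normalize_sequence,
)

# transition column order, per state k (1-based states):
#   0 M_k->M_{k+1}   1 M_k->I_k     2 M_k->D_{k+1}
#   3 I_k->M_{k+1}   4 I_k->I_k
#   5 D_k->M_{k+1}   6 D_k->D_{k+1}
TRANS_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

_NEG = -1.0e30


@dataclass
class ProfileHMM:
    """A pseudocounted match/insert/delete profile over the 20 residues."""

    family_name: str
    match_emissions: np.ndarray  # (K, 20)
    transitions: np.ndarray  # (K, 7)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    insert_emissions: np.ndarray | None = None  # defaults to background

    def __post_init__(self) -> None:
        if self.insert_emissions is None:
            self.insert_emissions = self.background.copy()
        me, tr = self.match_emissions, self.transitions
        if me.ndim != 2 or me.shape[1] != 20 or me.shape[0] < 1:
            raise ValueError("match_emissions must be (K, 20) with K >= 1")
        if tr.shape != (me.shape[0], 7):
            raise ValueError("transitions must be (K, 7)")
        for name, vec in (("background", self.background), ("insert_emissions", self.insert_emissions)):
            if abs(vec.sum() - 1.0) > 1e-9 or (vec <= 0).any():
                raise ValueError(f"{name} must be a positive probability vector")
        if (me <= 0).any() or np.abs(me.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("match emission rows must be positive and sum to 1")
        sums = np.stack([tr[:, 0] + tr[:, 1] + tr[:, 2], tr[:, 3] + tr[:, 4], tr[:, 5] + tr[:, 6]])
        if (tr <= 0).any() or np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("transition groups must be positive and sum to 1")
        # cached log-odds arrays for the scorers
        self._lods = np.zeros((self.n_match, 21))
        self._lods[:, :20] = np.log2(me / self.background[None, :])
        self._lods[:, X_INDEX] = 0.0  # X scores 0 against everything
        self._lt = np.log2(tr)

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        from .io_formats import AMINO_ACIDS

        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.match_emissions, axis=1))


@dataclass
class GumbelParams:
    """Location/scale of the null forward-score distribution (bits)."""

    mu: float
    lambda_g: float
    n_calib: int

    def __post_init__(self) -> None:
        if self.lambda_g <= 0:
            raise ValueError("degenerate Gumbel fit: lambda_g <= 0")
        if self.n_calib < 100:
            raise ValueError("calibration needs n_calib >= 100")


@dataclass
class HmmHit:
    protein_id: str
    family_name: str
    bit_score: float
    e_value: float
    tie: bool = False


def build_profile(
    seed: SeedAlignment,
    occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
    family_name: str = "",
) -> ProfileHMM:
    """Build a profile HMM from a seed alignment.

    Columns whose residue occupancy (non-gap fraction) is >= the threshold
    become match states.  Match emissions are Laplace-style mixtures of the
    observed counts with the background; transitions are counted from the
    implied per-row state paths with add-one smoothing.
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    rows = [r.upper() for r in seed.rows]
    n, width = seed.n_rows, seed.width
    occ = np.array([sum(1 for r in rows if r[c] != "-") / n for c in range(width)])
    match_cols = [c for c in range(width) if occ[c] >= occupancy_threshold]
    if not match_cols:
        raise ValueError("no columns pass the occupancy threshold")
    K = len(match_cols)
    counts = np.zeros((K, 20))
    for r in rows:
        for k, c in enumerate(match_cols):
            ch = r[c]
            if ch == "-" or ch == "X":
                continue  # X spreads no information
            counts[k, AA_INDEX[ch]] += 1.0
    n_obs = counts.sum(axis=1)
    me = (counts + pseudocount * BACKGROUND[None, :]) / (n_obs + pseudocount)[:, None]
    me = me / me.sum(axis=1, keepdims=True)

    # implied state path per row: match col -> M_k or D_k; residues in
    # non-match columns -> I_k at the current match index (inserts before
    # the first match state fall outside the local model and are dropped)
    match_set = set(match_cols)
    tcounts = np.zeros((K, 7))
    for r in rows:
        path: list[tuple[str, int]] = []
        k = 0
        for c in range(width):
            if c in match_set:
                k += 1
                path.append(("M" if r[c] != "-" else "D", k))
            elif r[c] != "-" and k >= 1:
                path.append(("I", k))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            col = {
                ("M", "M"): 0, ("M", "I"): 1, ("M", "D"): 2,
                ("I", "M"): 3, ("I", "I"): 4,
                ("D", "M"): 5, ("D", "D"): 6,
            }.get((s1, s2))
            if col is not None:
                tcounts[k1 - 1, col] += 1.0
    tr = np.empty((K, 7))
    for k in range(K):
        m = tcounts[k, 0:3] + 1.0
        i = tcounts[k, 3:5] + 1.0
        d = tcounts[k, 5:7] + 1.0
        tr[k] = np.concatenate([m / m.sum(), i / i.sum(), d / d.sum()])
    return ProfileHMM(family_name=family_name, match_emissions=me, transitions=tr)


@njit(cache=True)
def _log2addexp(a, b):
    if a < b:
        a, b = b, a
    if b - a < -40.0:  # below double precision of the sum
        return a
    return a + np.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def _viterbi_kernel(lods, lt, seq):
    K = lods.shape[0]
    L = seq.shape[0]
    entry = -np.log2(K)
    vm_prev = np.full(K, _NEG)
    vi_prev = np.full(K, _NEG)
    vd_prev = np.full(K, _NEG)
    ptr_m = np.zeros((L, K), dtype=np.int8)  # 0 entry, 1 MM, 2 IM, 3 DM
    ptr_i = np.zeros((L, K), dtype=np.int8)  # 0 from M, 1 from I
    ptr_d = np.zeros((L, K), dtype=np.int8)  # 0 from M, 1 from D
    best = _NEG
    bi = -1
    bk = -1
    for i in range(L):
        vm = np.full(K, _NEG)
        vi = np.full(K, _NEG)
        vd = np.full(K, _NEG)
        a = seq[i]
        for k in range(K):
            s = entry
            p = 0
            if k > 0:
                t = vm_prev[k - 1] + lt[k - 1, 0]
                if t > s:
                    s = t
                    p = 1
                t = vi_prev[k - 1] + lt[k - 1, 3]
                if t > s:
                    s = t
                    p = 2
                t = vd_prev[k - 1] + lt[k - 1, 5]
                if t > s:
                    s = t
                    p = 3
            vm[k] = s + lods[k, a]
            ptr_m[i, k] = p
            s2 = vm_prev[k] + lt[k, 1]
            t2 = vi_prev[k] + lt[k, 4]
            if s2 >= t2:
                vi[k] = s2
                ptr_i[i, k] = 0
            else:
                vi[k] = t2
                ptr_i[i, k] = 1
            if k > 0:
                s3 = vm[k - 1] + lt[k - 1, 2]
                t3 = vd[k - 1] + lt[k - 1, 6]
                if s3 >= t3:
                    vd[k] = s3
                    ptr_d[i, k] = 0
                else:
                    vd[k] = t3
                    ptr_d[i, k] = 1
            if vm[k] > best:
                best = vm[k]
                bi = i
                bk = k
        vm_prev, vi_prev, vd_prev = vm, vi, vd
    return best, bi, bk, ptr_m, ptr_i, ptr_d


@njit(cache=True)
def _forward_kernel(lods, lt, seq):
    K = lods.shape[0]
    L = seq.shape[0]
    entry = -np.log2(K)
    fm_prev = np.full(K, _NEG)
    fi_prev = np.full(K, _NEG)
    fd_prev = np.full(K, _NEG)
    total = _NEG
    for i in range(L):
        fm = np.full(K, _NEG)
        fi = np.full(K, _NEG)
        fd = np.full(K, _NEG)
        a = seq[i]
        for k in range(K):
            s = entry
            if k > 0:
                s = _log2addexp(s, fm_prev[k - 1] + lt[k - 1, 0])
                s = _log2addexp(s, fi_prev[k - 1] + lt[k - 1, 3])
                s = _log2addexp(s, fd_prev[k - 1] + lt[k - 1, 5])
            fm[k] = s + lods[k, a]
            fi[k] = _log2addexp(fm_prev[k] + lt[k, 1], fi_prev[k] + lt[k, 4])
            if k > 0:
                fd[k] = _log2addexp(fm[k - 1] + lt[k - 1, 2], fd[k - 1] + lt[k - 1, 6])
            total = _log2addexp(total, fm[k])
        fm_prev, fi_prev, fd_prev = fm, fi, fd
    return total


def _encoded(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_sequence(normalize_sequence(seq))


def score_viterbi(hmm: ProfileHMM, seq: str | np.ndarray) -> float:
    """Best single local alignment score in bits (log2 odds)."""
    enc = _encoded(seq)
    if enc.size == 0:
        raise ValueError("cannot score an empty sequence")
    best, _, _, _, _, _ = _viterbi_kernel(hmm._lods, hmm._lt, enc)
    return float(best)


def score_forward(hmm: ProfileHMM, seq: str | np.ndarray) -> float:
    """Log2 sum over all local alignments (bits); >= the Viterbi score."""
    enc = _encoded(seq)
    if enc.size == 0:
        raise ValueError("cannot score an empty sequence")
    return float(_forward_kernel(hmm._lods, hmm._lt, enc))


def viterbi_path(hmm: ProfileHMM, seq: str | np.ndarray) -> tuple[float, list[tuple[str, int, int]]]:
    """Viterbi score plus the state path.

    The path is a list of (state, match_state_index [1-based], residue_index
    [0-based, -1 for deletes]) in sequence order, covering only the locally
    aligned region.
    """
    enc = _encoded(seq)
    if enc.size == 0:
        raise ValueError("cannot score an empty sequence")
    best, bi, bk, ptr_m, ptr_i, ptr_d = _viterbi_kernel(hmm._lods, hmm._lt, enc)
    path: list[tuple[str, int, int]] = []
    state, i, k = "M", bi, bk
    while True:
        if state == "M":
            path.append(("M", k + 1, i))
            p = ptr_m[i, k]
            if p == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(p)]
            i, k = i - 1, k - 1
        elif state == "I":
            path.append(("I", k + 1, i))
            state = "M" if ptr_i[i, k] == 0 else "I"
            i = i - 1
        else:  # D: silent, same residue count
            path.append(("D", k + 1, -1))
            state = "M" if ptr_d[i, k] == 0 else "D"
            k = k - 1
    path.reverse()
    return float(best), path


def _censored_gumbel_mle(scores: np.ndarray, tail_fraction: float) -> tuple[float, float]:
    """ML Gumbel fit with the lower (1 - tail_fraction) of scores censored.

    Null forward scores have a near-exponential right tail that a bulk
    MLE badly underestimates; anchoring the likelihood on the upper order
    statistics (scores below the cut contribute only P(S <= cut)) gives
    E-values that are accurate where they matter.
    """
    from scipy.optimize import minimize

    tau = float(np.quantile(scores, 1.0 - tail_fraction))
    obs = scores[scores >= tau]
    n_cens = int((scores < tau).sum())

    def negll(params: np.ndarray) -> float:
        mu, log_beta = params
        beta = np.exp(log_beta)
        ll = stats.gumbel_r.logpdf(obs, loc=mu, scale=beta).sum()
        if n_cens:
            ll += n_cens * stats.gumbel_r.logcdf(tau, loc=mu, scale=beta)
        return -ll

    loc0, scale0 = stats.gumbel_r.fit(scores)
    res = minimize(negll, x0=np.array([loc0, np.log(scale0)]), method="Nelder-Mead")
    mu, beta = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, beta


def calibrate(
    hmm: ProfileHMM,
    n_random: int = 1000,
    mean_len: int = 400,
    seed: int = 0,
    tail_fraction: float = 0.3,
) -> GumbelParams:
    """Fit a Gumbel law to forward scores of background-emitted sequences.

    The fit is a left-censored maximum-likelihood fit on the upper
    ``tail_fraction`` of the null scores (``tail_fraction=1`` recovers the
    plain bulk MLE).
    """
    if n_random < 100:
        raise ValueError("calibration needs n_random >= 100")
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for i in range(n_random):
        seq = rng.choice(20, size=mean_len, p=hmm.background).astype(np.int8)
        scores[i] = _forward_kernel(hmm._lods, hmm._lt, seq)
    if tail_fraction >= 1.0:
        loc, scale = stats.gumbel_r.fit(scores)
    else:
        loc, scale = _censored_gumbel_mle(scores, tail_fraction)
    if scale <= 0:
        raise ValueError("degenerate Gumbel fit")
    return GumbelParams(mu=float(loc), lambda_g=float(1.0 / scale), n_calib=n_random)


def e_value(
    gumbel: GumbelParams,
    bit_score: float,
    n_targets: int,
    seq_len: int | None = None,
    calib_len: int | None = None,
) -> float:
    """Expected number of >= bit_score hits over n_targets random targets.

    When ``seq_len`` and ``calib_len`` are given, the score is first
    corrected by log2(seq_len / calib_len): the local sum-over-starts null
    score grows by one bit per doubling of target length.
    """
    if seq_len is not None and calib_len:
        bit_score = bit_score - np.log2(seq_len / calib_len)
    sf = stats.gumbel_r.sf(bit_score, loc=gumbel.mu, scale=1.0 / gumbel.lambda_g)
    return float(n_targets * sf)


def search_proteome(
    hmm: ProfileHMM,
    proteome: list[ProteinRecord],
    gumbel: GumbelParams,
    e_threshold: float = 1e-5,
    calib_len: int | None = None,
) -> list[HmmHit]:
    """Score every protein; return hits with E <= threshold, best first.

    E is computed over the size of the searched set, with the target-length
    correction applied when ``calib_len`` is given.
    """
    n = len(proteome)
    hits = []
    for rec in proteome:
        bits = score_forward(hmm, rec.sequence)
        ev = e_value(gumbel, bits, n, seq_len=len(rec.sequence), calib_len=calib_len)
        if ev <= e_threshold:
            hits.append(HmmHit(rec.protein_id, hmm.family_name, bits, ev))
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.protein_id))
    return hits


def annotate_top_hit(
    protein: ProteinRecord,
    family_db: list[ProfileHMM],
    gumbels: dict[str, GumbelParams] | None = None,
) -> HmmHit:
    """Label a protein by its top-scoring family model.

    Exact ties go to the lexicographically first family name with a warning
    flag; if every model scores -inf the sentinel label "other" is returned.
    """
    if not family_db:
        raise ValueError("need at least one family model")
    scored = []
    for hmm in family_db:
        bits = score_forward(hmm, protein.sequence)
        ev = float("nan")
        if gumbels and hmm.family_name in gumbels:
            ev = e_value(gumbels[hmm.family_name], bits, 1)
        scored.append((hmm.family_name, bits, ev))
    finite = [s for s in scored if s[1] > _NEG / 2]
    if not finite:
        return HmmHit(protein.protein_id, "other", float("-inf"), float("inf"))
    best_bits = max(s[1] for s in finite)
    winners = sorted(s for s in finite if s[1] == best_bits)
    tie = len(winners) > 1
    if tie:
        warnings.warn(
            f"HMM score tie for {protein.protein_id}: "
            + ", ".join(w[0] for w in winners),
            stacklevel=2,
        )
    name, bits, ev = winners[0]
    return HmmHit(protein.protein_id, name, bits, ev, tie=tie)
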