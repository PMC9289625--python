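"""Locus clustering, progressive multiple alignment and consensus calling.

Extended loci are clustered greedily (a locus joins a representative when
their best local alignment covers at least half of the shorter sequence at
>= 0.8 identity); clusters of at least five members are aligned with a
progressive aligner (k-mer cosine guide tree, profile-profile Needleman-
Wunsch with affine gaps, banded around the proportional diagonal for long
sequences) and a consensus is called per cluster with the match-ratio rule:
a column is a match column iff its non-gap fraction is >= match_ratio
(boundary inclusive) and emits its most frequent non-gap residue, ties
broken alphabetically; non-match columns are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._alignment import approx_local_overlap, local_overlap
from .rtscan import ExtendedLocus

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_GAP = 5
_LETTER = np.array(list("ACGTN-"))
# nucleotide column-score matrix: match +1, mismatch -1, N neutral
_S5 = np.full((5, 5), -1.0)
np.fill_diagonal(_S5, 1.0)
_S5[4, :] = 0.0
_S5[:, 4] = 0.0

GAP_OPEN = -5.0
GAP_EXTEND = -1.0
DEFAULT_BAND = 512
MIN_CLUSTER_MEMBERS = 5
MAX_SEQ_LEN = 15000


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _decode_row(row: np.ndarray) -> str:
    return "".join(_LETTER[row])


@dataclass
class LocusCluster:
    representative: str
    member_ids: list[str]
    eligible: bool
    min_cov: float


@dataclass
class MultipleAlignment:
    """Rows of equal length; ungapping a row recovers its input sequence."""

    ids: list[str]
    matrix: np.ndarray  # (rows, cols) int8 over {A,C,G,T,N,-}

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, i: int) -> str:
        return _decode_row(self.matrix[i])

    def ungapped(self, i: int) -> str:
        r = self.matrix[i]
        return _decode_row(r[r != _GAP])


@dataclass
class ConsensusRecord:
    """The pipeline's central product: one consensus per eligible cluster."""

    consensus_id: str
    seq: str
    species_id: str
    member_count: int
    match_columns: tuple[int, ...] = ()
    annotations: dict = field(default_factory=dict)


def cluster_loci(
    loci: list[ExtendedLocus],
    min_cov: float = 0.5,
    min_identity: float = 0.8,
    min_members: int = MIN_CLUSTER_MEMBERS,
    max_seq_len: int = MAX_SEQ_LEN,
) -> list[LocusCluster]:
    """Greedy coverage clustering of extended loci.

    A locus joins the first representative whose best local alignment covers
    >= min_cov of the shorter sequence at >= min_identity.  Loci longer than
    ``max_seq_len`` are not admitted.  Clusters below ``min_members`` are
    reported but flagged ineligible for consensus building.
    """
    admitted = [l for l in loci if len(l.seq) <= max_seq_len]
    order = sorted(admitted, key=lambda l: (-len(l.seq), l.locus_id))
    reps: list[ExtendedLocus] = []
    membership: dict[str, list[str]] = {}
    rep_seqs: dict[str, str] = {}
    for locus in order:
        placed = False
        for rep in reps:
            # seed-chain estimate settles clear cases without the O(nm) aligner
            cov_e, id_e = approx_local_overlap(locus.seq, rep.seq)
            if cov_e < min_cov - 0.1 or id_e < min_identity - 0.03:
                continue
            if cov_e >= min_cov + 0.05 and id_e >= min_identity + 0.03:
                membership[rep.locus_id].append(locus.locus_id)
                placed = True
                break
            _, cov, ident = local_overlap(locus.seq, rep.seq)
            if cov >= min_cov and ident >= min_identity:
                membership[rep.locus_id].append(locus.locus_id)
                placed = True
                break
        if not placed:
            reps.append(locus)
            membership[locus.locus_id] = [locus.locus_id]
            rep_seqs[locus.locus_id] = locus.seq
    return [
        LocusCluster(
            representative=rep.locus_id,
            member_ids=membership[rep.locus_id],
            eligible=len(membership[rep.locus_id]) >= min_members,
            min_cov=min_cov,
        )
        for rep in reps
    ]


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_counter(seq: str, k: int = 8) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _cosine_distance(a: Counter, b: Counter) -> float:
    if not a or not b:
        return 1.0
    shared = set(a) & set(b)
    dot = sum(a[x] * b[x] for x in shared)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    return 1.0 - dot / (na * nb)


def _guide_order(seqs: list[str]) -> list[tuple[int, int]]:
    """UPGMA join order on k-mer cosine distances (deterministic tie-breaks).

    Returns a list of (i, j) cluster-index joins; new clusters take index
    n, n+1, ... in join order.
    """
    n = len(seqs)
    counters = [_kmer_counter(s) for s in seqs]
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = _cosine_distance(counters[i], counters[j])
    active = list(range(n))
    sizes = {i: 1 for i in active}
    joins: list[tuple[int, int]] = []
    nxt = n
    while len(active) > 1:
        best = min(
            ((d, pair) for pair, d in dist.items() if pair[0] in active and pair[1] in active),
            key=lambda t: (round(t[0], 12), t[1]),
        )
        i, j = best[1]
        joins.append((i, j))
        active = [a for a in active if a not in (i, j)]
        for a in active:
            da = dist.pop((min(a, i), max(a, i)))
            db = dist.pop((min(a, j), max(a, j)))
            dist[(min(a, nxt), max(a, nxt))] = (da * sizes[i] + db * sizes[j]) / (
                sizes[i] + sizes[j]
            )
        dist = {p: d for p, d in dist.items() if i not in p and j not in p}
        sizes[nxt] = sizes[i] + sizes[j]
        active.append(nxt)
        nxt += 1
    return joins


def _profile(mat: np.ndarray) -> np.ndarray:
    """Column frequencies over {A,C,G,T,N} (gap mass excluded), (cols, 5)."""
    rows, cols = mat.shape
    out = np.zeros((cols, 5))
    for s in range(5):
        out[:, s] = (mat == s).sum(axis=0)
    return out / rows


def _band_limits(n: int, m: int, band: int | None) -> tuple[np.ndarray, np.ndarray]:
    centers = np.round(np.arange(n + 1) * (m / n if n else 0)).astype(int)
    if band is None:
        lo = np.zeros(n + 1, dtype=int)
        hi = np.full(n + 1, m, dtype=int)
    else:
        w = max(band, abs(n - m) + 32)
        lo = np.clip(centers - w, 0, m)
        hi = np.clip(centers + w, 0, m)
    lo[0], hi[n] = 0, m
    return lo, hi


def _align_profiles(
    matA: np.ndarray,
    matB: np.ndarray,
    band: int | None,
) -> np.ndarray:
    """Align two alignment blocks; returns the merged (rows, cols) matrix."""
    n, m = matA.shape[1], matB.shape[1]
    if n == 0 or m == 0:
        gapA = np.full((matA.shape[0], m), _GAP, dtype=np.int8)
        gapB = np.full((matB.shape[0], n), _GAP, dtype=np.int8)
        return np.vstack([np.hstack([matA, gapA]), np.hstack([gapB, matB])])
    fA = _profile(matA)
    fB = _profile(matB)
    PB = fB @ _S5.T  # (m, 5): PB[j] . fA[i] = column score

    lo, hi = _band_limits(n, m, band)
    NEG = -1e18
    M_prev = np.full(m + 1, NEG)
    X_prev = np.full(m + 1, NEG)
    Y_prev = np.full(m + 1, NEG)
    M_prev[0] = 0.0
    if m >= 1:
        j = np.arange(1, m + 1)
        Y_prev[1:] = GAP_OPEN + (j - 1) * GAP_EXTEND
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        l, h = int(lo[i]), int(hi[i])
        sl = slice(l, h + 1)
        M_cur = np.full(m + 1, NEG)
        X_cur = np.full(m + 1, NEG)
        Y_cur = np.full(m + 1, NEG)
        # X: gap in B, consume column i of A (vertical move)
        x_from_m = M_prev[sl] + GAP_OPEN
        x_from_x = X_prev[sl] + GAP_EXTEND
        X_cur[sl] = np.maximum(x_from_m, x_from_x)
        ptrX[i, sl] = x_from_x > x_from_m
        if l == 0:
            X_cur[0] = GAP_OPEN + (i - 1) * GAP_EXTEND
            ptrX[i, 0] = 0 if i == 1 else 1
        # M: diagonal
        jl = max(l, 1)
        mp, xp, yp = M_prev[jl - 1 : h], X_prev[jl - 1 : h], Y_prev[jl - 1 : h]
        best_val = np.maximum(np.maximum(mp, xp), yp)
        best_state = np.where(best_val == mp, 0, np.where(best_val == xp, 1, 2))
        scores = PB[jl - 1 : h] @ fA[i - 1]
        M_cur[jl : h + 1] = best_val + scores
        ptrM[i, jl : h + 1] = best_state
        # Y: gap in A, consume columns of B (horizontal move); within-row
        # recursion unrolled via a running prefix max over the band
        band_m = M_cur[sl]
        t = np.where(band_m > NEG / 2, band_m - jj[sl] * GAP_EXTEND, NEG)
        run = np.maximum.accumulate(t)
        yl = max(jl, l + 1)  # Y needs an in-band left neighbour
        if h >= yl:
            y_j = np.arange(yl, h + 1)
            prev_run = run[y_j - 1 - l]
            y_val = np.where(
                prev_run > NEG / 2,
                GAP_OPEN + (y_j - 1) * GAP_EXTEND + prev_run,
                NEG,
            )
            Y_cur[yl : h + 1] = y_val
            from_m = t[y_j - 1 - l] >= prev_run - 1e-9
            ptrY[i, yl : h + 1] = np.where(from_m, 0, 1)
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur

    # traceback
    finals = [M_prev[m], X_prev[m], Y_prev[m]]
    state = int(np.argmax(finals))
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i == 0:
            ops.append("B")
            j -= 1
            continue
        if j == 0:
            ops.append("A")
            i -= 1
            continue
        if state == 0:
            ops.append("D")
            state = int(ptrM[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("A")
            state = 0 if ptrX[i, j] == 0 else 1
            i -= 1
        else:
            nxt = 0 if ptrY[i, j] == 0 else 2
            ops.append("B")
            state = nxt
            j -= 1
    ops.reverse()

    colsA = []
    colsB = []
    ai = bi = 0
    for op in ops:
        if op == "D":
            colsA.append(ai)
            colsB.append(bi)
            ai += 1
            bi += 1
        elif op == "A":
            colsA.append(ai)
            colsB.append(-1)
            ai += 1
        else:
            colsA.append(-1)
            colsB.append(bi)
            bi += 1
    total = len(ops)
    merged = np.full((matA.shape[0] + matB.shape[0], total), _GAP, dtype=np.int8)
    colsA = np.array(colsA)
    colsB = np.array(colsB)
    selA = colsA >= 0
    selB = colsB >= 0
    merged[: matA.shape[0], selA] = matA[:, colsA[selA]]
    merged[matA.shape[0] :, selB] = matB[:, colsB[selB]]
    return merged


def align_cluster(
    seqs: list[tuple[str, str]],
    band: int = DEFAULT_BAND,
    full_dp_limit: int = 4_000_000,
) -> MultipleAlignment:
    """Progressive multiple alignment of 1-50 sequences.

    Full dynamic programming is used when the profile-pair DP table is small;
    longer pairs are banded around the proportional diagonal (half-width
    ``band``, widened by any length difference).  Deterministic given input.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) > 50:
        raise ValueError("at most 50 sequences per cluster alignment")
    ids = [sid for sid, _ in seqs]
    if len(seqs) == 1:
        return MultipleAlignment(ids=ids, matrix=_encode(seqs[0][1])[None, :])
    joins = _guide_order([s for _, s in seqs])
    nodes: dict[int, tuple[list[int], np.ndarray]] = {
        i: ([i], _encode(s)[None, :]) for i, (_, s) in enumerate(seqs)
    }
    nxt = len(seqs)
    for i, j in joins:
        rows_i, mat_i = nodes.pop(i)
        rows_j, mat_j = nodes.pop(j)
        use_band = band if mat_i.shape[1] * mat_j.shape[1] > full_dp_limit else None
        merged = _align_profiles(mat_i, mat_j, use_band)
        nodes[nxt] = (rows_i + rows_j, merged)
        nxt += 1
    (rows, mat), = nodes.values()
    order = np.argsort(rows)
    return MultipleAlignment(ids=[ids[rows[k]] for k in order], matrix=mat[order])


def consensus_from_msa(
    msa: MultipleAlignment,
    match_ratio: float = 0.5,
    consensus_id: str = "consensus",
    species_id: str = "unknown",
) -> ConsensusRecord:
    """Call a consensus with the match-ratio rule (boundary inclusive)."""
    mat = msa.matrix
    rows = mat.shape[0]
    nongap = mat != _GAP
    frac = nongap.sum(axis=0) / rows
    match_cols = np.nonzero(frac >= match_ratio)[0]
    letters = []
    for c in match_cols:
        col = mat[nongap[:, c], c]
        counts = np.bincount(col, minlength=5)[:5]
        # most frequent residue; ties broken by alphabetical letter order
        order = sorted(range(5), key=lambda s: (-counts[s], _LETTER[s]))
        letters.append(_LETTER[order[0]])
    return ConsensusRecord(
        consensus_id=consensus_id,
        seq="".join(letters),
        species_id=species_id,
        member_count=rows,
        match_columns=tuple(int(c) for c in match_cols),
    )


def build_consensi(
    loci: list[ExtendedLocus],
    species_id: str,
    min_members: int = MIN_CLUSTER_MEMBERS,
    match_ratio: float = 0.5,
    min_cov: float = 0.5,
    max_members: int = 50,
    band: int = DEFAULT_BAND,
) -> tuple[list[ConsensusRecord], list[LocusCluster], dict[str, MultipleAlignment]]:
    """Cluster loci, align each eligible cluster and call one consensus each."""
    clusters = cluster_loci(loci, min_cov=min_cov, min_members=min_members)
    by_id = {l.locus_id: l for l in loci}
    consensi = []
    alignments: dict[str, MultipleAlignment] = {}
    for k, cluster in enumerate(clusters):
        if not cluster.eligible:
            continue
        member_ids = cluster.member_ids[:max_members]
        seqs = [(mid, by_id[mid].seq) for mid in member_ids]
        msa = align_cluster(seqs, band=band)
        cid = f"{species_id}|cluster{k}|n={len(seqs)}"
        alignments[cid] = msa
        consensi.append(
            consensus_from_msa(msa, match_ratio=match_ratio, consensus_id=cid, species_id=species_id)
        )
    return consensi, clusters, alignments
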