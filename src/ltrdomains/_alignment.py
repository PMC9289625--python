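"""Shared pairwise-alignment helpers.

Global/local pairwise alignment goes through ``Bio.Align.PairwiseAligner``
with a fixed nucleotide scoring scheme (match 1, mismatch -1, gap open -5,
gap extend -1).  Identity is defined as identities / alignment length, i.e.
gap columns count against identity.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

NT_MATCH = 1
NT_MISMATCH = -1
NT_GAP_OPEN = -5
NT_GAP_EXTEND = -1


@lru_cache(maxsize=None)
def _nt_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode=mode,
        match_score=NT_MATCH,
        mismatch_score=NT_MISMATCH,
        open_gap_score=NT_GAP_OPEN,
        extend_gap_score=NT_GAP_EXTEND,
    )
    return aligner


@lru_cache(maxsize=None)
def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-11,
        extend_gap_score=-1,
    )
    return aligner


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity between two nucleotide sequences.

    identity = identities / (identities + mismatches + gap columns).
    """
    if not a or not b:
        return 0.0
    aln = _nt_aligner("global").align(a, b)[0]
    counts = aln.counts()
    denom = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / denom if denom else 0.0


def local_overlap(a: str, b: str) -> tuple[float, float, float]:
    """Best local alignment of *a* vs *b*.

    Returns ``(score, coverage_of_shorter, identity_within_alignment)``.
    Coverage is the aligned length on the shorter sequence divided by the
    shorter sequence's length; identity counts internal gap columns of the
    local alignment against identity.
    """
    if not a or not b:
        return 0.0, 0.0, 0.0
    alns = _nt_aligner("local").align(a, b)
    aln = alns[0]
    counts = aln.counts()
    blocks = aln.aligned
    len_a = sum(int(e - s) for s, e in blocks[0])
    len_b = sum(int(e - s) for s, e in blocks[1])
    shorter = min(len(a), len(b))
    coverage = min(len_a, len_b) / shorter if shorter else 0.0
    denom = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / denom if denom else 0.0
    return float(aln.score), coverage, identity


def local_aa_score(a: str, b: str) -> float:
    """BLOSUM62 local-alignment score between two amino-acid sequences."""
    if not a or not b:
        return 0.0
    try:
        return float(_aa_aligner().score(a, b))
    except ValueError:
        # sequences containing letters outside the matrix alphabet
        clean_a = "".join(c for c in a if c in "ACDEFGHIKLMNPQRSTVWYBZX*")
        clean_b = "".join(c for c in b if c in "ACDEFGHIKLMNPQRSTVWYBZX*")
        if not clean_a or not clean_b:
            return 0.0
        return float(_aa_aligner().score(clean_a, clean_b))


def approx_local_overlap(
    a: str,
    b: str,
    k: int = 11,
    diag_window: int = 200,
    max_kmer_occurrences: int = 4,
) -> tuple[float, float]:
    """Seed-chain estimate of (coverage_of_shorter, identity) for a local match.

    Exact k-mer matches between the two sequences are bucketed by diagonal;
    the densest diagonal band gives the matched span on the shorter sequence
    (coverage estimate) and the k-mer hit rate within that span, whose k-th
    root estimates per-base identity (a hit survives iff all k bases match).
    Used to fast-path clear clustering decisions before the O(nm) aligner.
    """
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    if len(shorter) < k:
        return 0.0, 0.0
    index: dict[str, list[int]] = {}
    for j in range(len(longer) - k + 1):
        bucket = index.setdefault(longer[j : j + k], [])
        if len(bucket) < max_kmer_occurrences:
            bucket.append(j)
    by_band: dict[int, set[int]] = {}
    for i in range(len(shorter) - k + 1):
        for j in index.get(shorter[i : i + k], ()):
            by_band.setdefault((j - i) // diag_window, set()).add(i)
    if not by_band:
        return 0.0, 0.0
    # merge each band with its neighbour to tolerate diagonal drift
    best_hits: set[int] = set()
    for band, hits in by_band.items():
        combined = hits | by_band.get(band + 1, set())
        if len(combined) > len(best_hits):
            best_hits = combined
    lo, hi = min(best_hits), max(best_hits) + k
    coverage = (hi - lo) / len(shorter)
    hit_rate = len(best_hits) / max(hi - lo - k + 1, 1)
    identity = min(hit_rate, 1.0) ** (1.0 / k)
    return coverage, identity


def kmer_set(seq: str, k: int = 11) -> set:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def kmer_containment(a: str, b: str, k: int = 11) -> float:
    """Fraction of the smaller sequence's k-mers shared with the other.

    Cheap prefilter used before committing to an O(nm) alignment.
    """
    sa, sb = kmer_set(a, k), kmer_set(b, k)
    if not sa or not sb:
        return 0.0
    small, big = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    return len(small & big) / len(small)
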