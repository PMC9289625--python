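"""RT-anchored discovery of LTR-retrotransposon loci.

Translated profile search with the PSSM engine, merging of overlapping hits,
size filtering to the expected reverse-transcriptase coding span (520-840 bp),
per-species identity clustering with a member cap, and extension of each hit
by flanking sequence to capture the surrounding element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._alignment import global_identity, kmer_containment
from .pssm import DomainProfile, scan_profiles
from .simulate import _revcomp

MIN_RT_NT = 520
MAX_RT_NT = 840
DEFAULT_FLANK = 5000


@dataclass
class RTHit:
    """A merged reverse-transcriptase hit on a contig (0-based half-open)."""

    species_id: str
    contig: str
    start: int
    end: int
    strand: str
    best_score: float
    best_profile: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ExtendedLocus:
    """An RT hit grown by flanking sequence, with its extracted sequence."""

    hit: RTHit
    start: int
    end: int
    seq: str

    @property
    def locus_id(self) -> str:
        h = self.hit
        return f"{h.species_id}|{h.contig}|{self.start}-{self.end}|{h.strand}"


@dataclass
class IdentityCluster:
    """A greedy identity cluster with a representative and a member cap."""

    representative: str
    members: list[str]  # capped, longest first
    identity_threshold: float
    n_total: int = 0
    all_members: list[str] = field(default_factory=list)


def merge_hits(hits: list[RTHit]) -> list[RTHit]:
    """Merge overlapping hit intervals per contig, keeping the max score.

    Idempotent: merging already-merged hits is a no-op.
    """
    by_contig: dict[tuple[str, str], list[RTHit]] = {}
    for h in hits:
        by_contig.setdefault((h.species_id, h.contig), []).append(h)
    merged: list[RTHit] = []
    for key in sorted(by_contig):
        group = sorted(by_contig[key], key=lambda h: (h.start, h.end))
        current = None
        for h in group:
            if current is None or h.start >= current.end:
                current = RTHit(**vars(h))
                merged.append(current)
            else:
                current.end = max(current.end, h.end)
                if h.best_score > current.best_score:
                    current.best_score = h.best_score
                    current.best_profile = h.best_profile
                    current.strand = h.strand
    return merged


def scan_rt(
    genome: list[tuple[str, str]],
    rt_profiles: list[DomainProfile],
    score_threshold: float | None = None,
    species_id: str = "unknown",
) -> list[RTHit]:
    """Scan a genome for reverse-transcriptase regions.

    Each profile slides over all six translated frames of each contig; window
    scores at or above the threshold become raw hits, which are projected to
    nucleotide coordinates and merged when overlapping.
    """
    raw: list[RTHit] = []
    for contig, seq in genome:
        for rh in scan_profiles(seq, rt_profiles, threshold=score_threshold):
            raw.append(
                RTHit(
                    species_id=species_id,
                    contig=contig,
                    start=rh.nt_start,
                    end=rh.nt_end,
                    strand=rh.strand,
                    best_score=rh.score,
                    best_profile=rh.profile,
                )
            )
    return merge_hits(raw)


def filter_size(hits: list[RTHit], min_nt: int = MIN_RT_NT, max_nt: int = MAX_RT_NT) -> list[RTHit]:
    """Keep hits whose merged span is within [min_nt, max_nt], bounds inclusive."""
    return [h for h in hits if min_nt <= h.span <= max_nt]


def extend_loci(
    hits: list[RTHit],
    genome: list[tuple[str, str]],
    flank: int = DEFAULT_FLANK,
) -> list[ExtendedLocus]:
    """Grow each hit by *flank* nt per side, clamped to contig bounds.

    Sequences of minus-strand hits are reverse-complemented so all loci read
    in element orientation.
    """
    contigs = dict(genome)
    loci = []
    for h in hits:
        if h.contig not in contigs:
            raise KeyError(f"contig not found: {h.contig}")
        seq = contigs[h.contig]
        start = max(0, h.start - flank)
        end = min(len(seq), h.end + flank)
        sub = seq[start:end]
        if h.strand == "-":
            sub = _revcomp(sub)
        loci.append(ExtendedLocus(hit=h, start=start, end=end, seq=sub))
    return loci


def cluster_identity(
    seqs: list[tuple[str, str]],
    threshold: float = 0.95,
    cap: int | None = 50,
    prefilter_k: int = 11,
) -> list[IdentityCluster]:
    """Greedy incremental clustering by global-alignment identity.

    Sequences are sorted by length descending (ties broken by id); each joins
    the first existing representative with identity >= threshold, else founds
    a new cluster.  Each cluster reports at most *cap* members, longest first
    (``cap=None`` disables the cap).
    """
    order = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []
    membership: dict[str, list[str]] = {}
    for sid, seq in order:
        placed = False
        for rid, rseq in reps:
            # cheap k-mer screen before the O(nm) alignment; only sound for
            # high identity thresholds where shared k-mers must survive
            if threshold >= 0.8 and kmer_containment(seq, rseq, k=prefilter_k) < 0.05:
                continue
            if global_identity(seq, rseq) >= threshold:
                membership[rid].append(sid)
                placed = True
                break
        if not placed:
            reps.append((sid, seq))
            membership[sid] = [sid]
    clusters = []
    for rid, _ in reps:
        members = membership[rid]
        capped = members if cap is None else members[:cap]
        clusters.append(
            IdentityCluster(
                representative=rid,
                members=list(capped),
                identity_threshold=threshold,
                n_total=len(members),
                all_members=list(members),
            )
        )
    return clusters
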