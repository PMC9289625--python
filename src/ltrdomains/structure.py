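"""Full-length element characterization.

LTR-pair detection by exact k-mer seeding between positions whose offset lies
within the allowed distance range, X-drop extension of collinear seed groups
into a direct-repeat pair, and optional snapping of repeat termini to the
canonical TG...CA motif; plus TIR/ORF/PBS/PPT annotation, dual-RNase-H
detection, a self dot-plot, and divergence-limited genome masking/coverage.

The distance constraint is interpreted as the offset between the LTR start
positions.  Divergence for masking is mismatches / alignment length of the
accepted local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pssm import DomainProfile, scan_frame_scores
from .simulate import ProfileLibrary, _revcomp

DEFAULT_MIN_DIST = 5000
DEFAULT_MAX_DIST = 20000
DEFAULT_MAX_LTR = 3000
DEFAULT_MIN_LTR = 100
DEFAULT_MIN_LTR_IDENTITY = 0.85
SEED_K = 20


@dataclass
class PBSRecord:
    start: int  # relative to the search window
    end: int
    trna: str
    match_len: int


@dataclass
class PPTRecord:
    start: int  # relative to the search window
    end: int
    purine_fraction: float


@dataclass
class OrfRecord:
    start: int
    end: int  # includes the stop codon when one terminates the ORF
    strand: str
    frame: int
    aa_length: int  # excludes the stop


@dataclass
class ElementModel:
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    tir_len: int = 0
    pbs: PBSRecord | None = None
    ppt: PPTRecord | None = None
    orfs: list[OrfRecord] = field(default_factory=list)
    rnaseh_copy_count: int = 0
    orientation: str = "+"  # element sense relative to the contig

    @property
    def ltr_len(self) -> int:
        return self.ltr5[1] - self.ltr5[0]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MaskedAnnotation:
    intervals: dict[str, list[tuple[int, int]]]
    masked_bp: int
    assembly_bp: int
    gap_bp: int

    @property
    def coverage(self) -> float:
        return self.masked_bp / self.assembly_bp if self.assembly_bp else 0.0

    @property
    def coverage_excluding_gaps(self) -> float:
        denom = self.assembly_bp - self.gap_bp
        return self.masked_bp / denom if denom else 0.0


# ---------------------------------------------------------------------------
# LTR pair detection


def _xdrop_extend(match: np.ndarray, start: int, direction: int, xdrop: float = 25.0) -> int:
    """Extend from *start* along *match* (bool array) until the score drops.

    Scoring +1 per match, -2 per mismatch; returns the last index (inclusive)
    of the maximal-scoring extension, or start - direction when no position
    improves the score.
    """
    best = -1.0
    best_i = start - direction
    score = 0.0
    i = start
    n = len(match)
    while 0 <= i < n:
        score += 1.0 if match[i] else -2.0
        if score > best:
            best = score
            best_i = i
        elif best - score > xdrop:
            break
        i += direction
    return best_i


def _motif_bonus(seq: str, pos: int, delta: int, motif: str, terminal: str) -> float:
    """Evidence bonus for the canonical TG/CA terminus at a candidate boundary."""
    n = len(seq)
    if terminal == "start":
        a, b = pos, pos + len(motif)
    else:
        a, b = pos - len(motif), pos
    if a < 0 or b + delta > n:
        return 0.0
    present = (seq[a:b] == motif) + (seq[a + delta : b + delta] == motif)
    return (0.0, 1.2, 3.0)[present]


# changepoint log-likelihood weights: repeat interior ~90% match vs ~25%
# background match for random nucleotides
_W_MATCH = 1.28
_W_MISMATCH = -2.04


def _refine_boundary(
    seq: str,
    match: np.ndarray,
    pos: int,
    delta: int,
    terminal: str,
    radius: int = 15,
    use_motif: bool = True,
) -> int:
    """Refine a repeat terminus by maximum-likelihood changepoint scoring.

    Candidates within ``radius`` of the X-drop boundary are scored by the
    changepoint log-likelihood of the match/mismatch profile, plus a soft
    bonus when the canonical TG (repeat start) or CA (repeat end) terminus is
    present in one or both repeat copies at the candidate.
    """
    n = len(match)
    lo = max(0, pos - radius)
    hi = min(n, pos + radius + 1)
    if hi <= lo:
        return pos
    w = np.where(match[lo:hi], _W_MATCH, _W_MISMATCH)
    csum = np.concatenate([[0.0], np.cumsum(w)])
    best_pos, best_score = pos, -np.inf
    motif = "TG" if terminal == "start" else "CA"
    for c in range(lo, hi + (terminal == "end")):
        if terminal == "start":
            # positions c..hi-1 are inside the repeat
            ll = csum[hi - lo] - csum[c - lo]
        else:
            # positions lo..c-1 are inside the repeat
            ll = csum[c - lo]
        bonus = _motif_bonus(seq, c, delta, motif, terminal) if use_motif else 0.0
        score = ll + bonus
        if score > best_score + 1e-9:
            best_score, best_pos = score, c
    return best_pos


def find_ltr_pairs(
    contig_seq: str,
    contig: str = "contig",
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
    max_ltr_len: int = DEFAULT_MAX_LTR,
    min_ltr_identity: float = DEFAULT_MIN_LTR_IDENTITY,
    min_ltr_len: int = DEFAULT_MIN_LTR,
    seed_k: int = SEED_K,
    min_seeds: int = 3,
    tgca_polish: bool = True,
) -> list[ElementModel]:
    """Detect direct-repeat (LTR) pairs on one contig.

    Exact ``seed_k``-mer matches between positions whose offset is within
    [min_dist, max_dist] are grouped by offset, extended by X-drop into a
    repeat pair, optionally snapped to TG...CA termini, and filtered by repeat
    length and identity.  Overlapping candidates are resolved by highest
    identity x length.
    """
    seq = contig_seq.upper()
    n = len(seq)
    if n < min_dist + seed_k:
        return []
    positions: dict[str, list[int]] = {}
    for i in range(n - seed_k + 1):
        word = seq[i : i + seed_k]
        if "N" in word:
            continue
        positions.setdefault(word, []).append(i)

    by_offset: dict[int, list[int]] = {}
    for plist in positions.values():
        if len(plist) < 2:
            continue
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                delta = plist[b] - plist[a]
                if min_dist <= delta <= max_dist:
                    by_offset.setdefault(delta, []).append(plist[a])

    # group nearby offsets (indel tolerance) and extend each group
    offsets = sorted(by_offset)
    groups: list[list[int]] = []
    for off in offsets:
        if groups and off - groups[-1][-1] <= 30:
            groups[-1].append(off)
        else:
            groups.append([off])

    candidates: list[ElementModel] = []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for group in groups:
        delta = int(np.median([off for off in group for _ in by_offset[off]]))
        limit = n - delta
        all_seeds = sorted({p for off in group for p in by_offset[off] if p < limit})
        if len(all_seeds) < min_seeds:
            continue
        # split seed runs separated by more than one LTR length: same-offset
        # seed groups can span distinct element copies on one contig
        chains: list[list[int]] = [[all_seeds[0]]]
        for p in all_seeds[1:]:
            if p - chains[-1][-1] > max_ltr_len:
                chains.append([p])
            else:
                chains[-1].append(p)
        for seeds in chains:
            if len(seeds) < min_seeds:
                continue
            match = arr[:limit] == arr[delta : delta + limit]
            lo_seed = seeds[0]
            hi_seed = min(seeds[-1] + seed_k - 1, limit - 1)
            left = _xdrop_extend(match, lo_seed, -1)
            right = _xdrop_extend(match, hi_seed, +1)
            start, end = left, right + 1
            start = _refine_boundary(seq, match, start, delta, "start", use_motif=tgca_polish)
            end = _refine_boundary(seq, match, end, delta, "end", use_motif=tgca_polish)
            start = max(0, start)
            end = min(end, limit)
            if end - start < min_ltr_len or end - start > max_ltr_len:
                continue
            identity = float(match[start:end].mean())
            if identity < min_ltr_identity:
                continue
            candidates.append(
                ElementModel(
                    contig=contig,
                    start=start,
                    end=end + delta,
                    ltr5=(start, end),
                    ltr3=(start + delta, end + delta),
                    ltr_identity=identity,
                )
            )

    candidates.sort(key=lambda c: (-(c.ltr_identity * c.ltr_len), c.start))
    accepted: list[ElementModel] = []
    for c in candidates:
        if all(c.end <= a.start or a.end <= c.start for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda c: c.start)
    return accepted


# ---------------------------------------------------------------------------
# feature annotation


def detect_tir(ltr_seq: str, max_tir: int = 12, min_tir: int = 3) -> int:
    """Longest terminal inverted repeat length within [min_tir, max_tir]; 0 if none."""
    if len(ltr_seq) < 2 * max_tir:
        return 0
    for t in range(max_tir, min_tir - 1, -1):
        if _revcomp(ltr_seq[:t]) == ltr_seq[-t:]:
            return t
    return 0


def find_orfs(internal_seq: str, min_aa: int = 300, any_start: bool = False) -> list[OrfRecord]:
    """Maximal start->stop spans per frame on both strands, length-sorted.

    With the default ATG requirement, an ORF runs from the first ATG after
    the previous stop to the next stop; ``any_start`` instead starts right
    after the previous stop.  Reported aa length excludes the stop.
    """
    seq = internal_seq.upper()
    n = len(seq)
    results: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            i = 0
            region_start = 0
            while i <= len(codons):
                if i == len(codons) or codons[i] in ("TAA", "TAG", "TGA"):
                    # close the open region [region_start, i)
                    j = region_start
                    if not any_start:
                        while j < i and codons[j] != "ATG":
                            j += 1
                    if j < i and i - j >= min_aa:
                        nt_start = frame + 3 * j
                        nt_end = frame + 3 * i + (3 if i < len(codons) else 0)
                        if strand == "-":
                            nt_start, nt_end = n - nt_end, n - nt_start
                        results.append(
                            OrfRecord(
                                start=nt_start,
                                end=nt_end,
                                strand=strand,
                                frame=frame,
                                aa_length=i - j,
                            )
                        )
                    region_start = i + 1
                i += 1
    results.sort(key=lambda o: (-o.aa_length, o.start))
    return results


def detect_pbs(
    seq_downstream_of_ltr5: str,
    trna_library: list[tuple[str, str]],
    window: int = 30,
    min_match: int = 12,
    max_match: int = 18,
) -> PBSRecord | None:
    """Find the reverse complement of a tRNA 3' terminus just inside the 5' LTR.

    Returns the best candidate (longest match, then closest to the LTR) or
    None when no tRNA tail complement of at least ``min_match`` nt occurs in
    the window.
    """
    target = seq_downstream_of_ltr5[:window].upper()
    best: PBSRecord | None = None
    for label, trna in trna_library:
        for t in range(min(max_match, len(trna)), min_match - 1, -1):
            probe = _revcomp(trna[-t:]).upper()
            idx = target.find(probe)
            if idx < 0:
                continue
            cand = PBSRecord(start=idx, end=idx + t, trna=label, match_len=t)
            if best is None or (cand.match_len, -cand.start) > (best.match_len, -best.start):
                best = cand
            break
    return best


def detect_ppt(
    seq_upstream_of_ltr3: str,
    window: int = 50,
    min_len: int = 10,
    min_purine: float = 0.85,
) -> PPTRecord | None:
    """Highest-purine-fraction run of >= min_len within the window before the 3' LTR.

    Positions are relative to the examined window (the last ``window`` nt of
    the supplied sequence).
    """
    tail = seq_upstream_of_ltr3[-window:].upper()
    w = len(tail)
    if w < min_len:
        return None
    purine = np.fromiter((c in "AG" for c in tail), dtype=float, count=w)
    csum = np.concatenate([[0.0], np.cumsum(purine)])
    best: PPTRecord | None = None
    for i in range(w - min_len + 1):
        for j in range(i + min_len, w + 1):
            frac = (csum[j] - csum[i]) / (j - i)
            if frac < min_purine:
                continue
            cand = PPTRecord(start=i, end=j, purine_fraction=float(frac))
            if (
                best is None
                or (cand.purine_fraction, cand.end - cand.start, cand.start)
                > (best.purine_fraction, best.end - best.start, best.start)
            ):
                best = cand
    return best


def detect_dual_rnaseh(
    polyprotein_aa: str,
    rnaseh_profile: DomainProfile,
    threshold: float | None = None,
) -> int:
    """Count non-overlapping RNase H profile hits on a polyprotein."""
    from .pssm import DEFAULT_BITS_PER_COLUMN

    cutoff = threshold if threshold is not None else DEFAULT_BITS_PER_COLUMN * len(rnaseh_profile)
    scores = scan_frame_scores(polyprotein_aa, rnaseh_profile)
    L = len(rnaseh_profile)
    hits = [(float(scores[i]), int(i)) for i in np.nonzero(scores >= cutoff)[0]]
    hits.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[int] = []
    for _, pos in hits:
        if all(pos + L <= a or a + L <= pos for a in accepted):
            accepted.append(pos)
    return len(accepted)


def annotate_element(
    contig_seq: str,
    model: ElementModel,
    library: ProfileLibrary,
    min_orf_aa: int = 300,
    sense_orfs_only: bool = True,
) -> ElementModel:
    """Fill TIR, PBS, PPT, ORFs and the RNase-H copy count of a detected pair.

    An LTR pair carries no strand information, so both orientations of the
    internal region are annotated and the one with the stronger PBS/PPT
    evidence (longest PBS match, then PPT presence) is kept; with
    ``sense_orfs_only`` only ORFs on the element's sense strand are reported.
    """
    seq = contig_seq.upper()
    ltr_seq = seq[model.ltr5[0] : model.ltr5[1]]
    model.tir_len = detect_tir(ltr_seq)
    internal = seq[model.ltr5[1] : model.ltr3[0]]
    scored = []
    for orientation, s in (("+", internal), ("-", _revcomp(internal))):
        pbs = detect_pbs(s, list(library.trnas))
        ppt = detect_ppt(s)
        key = (pbs.match_len if pbs else 0, 1 if ppt else 0, orientation == "+")
        scored.append((key, orientation, s, pbs, ppt))
    scored.sort(key=lambda t: t[0], reverse=True)
    _, orientation, oriented, pbs, ppt = scored[0]
    model.orientation = orientation
    model.pbs = pbs
    model.ppt = ppt
    orfs = find_orfs(oriented, min_aa=min_orf_aa)
    if sense_orfs_only:
        orfs = [o for o in orfs if o.strand == "+"]
    model.orfs = orfs
    rh_profiles = [p for p in library.profiles if p.family == "RNaseH"]
    if rh_profiles and model.orfs:
        count = 0
        for orf in model.orfs:
            sub = oriented[orf.start : orf.end]
            aa = _translate_orf(sub, orf.strand)
            count = max(count, detect_dual_rnaseh(aa, rh_profiles[0]))
        model.rnaseh_copy_count = count
    return model


def _translate_orf(nt: str, strand: str) -> str:
    from Bio.Seq import Seq

    s = nt if strand == "+" else _revcomp(nt)
    s = s[: 3 * (len(s) // 3)]
    return str(Seq(s).translate())


# ---------------------------------------------------------------------------
# dot plot


def dotplot(seq: str, word: int = 15) -> list[tuple[int, int, str]]:
    """All exact word self-matches of *seq*, both strands.

    Returns (x, y, strand) coordinate pairs; the main diagonal is included
    and the output is symmetric: (x, y) present implies (y, x) present.
    """
    seq = seq.upper()
    n = len(seq)
    fwd: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        fwd.setdefault(seq[i : i + word], []).append(i)
    points: list[tuple[int, int, str]] = []
    for w, plist in fwd.items():
        for x in plist:
            for y in plist:
                points.append((x, y, "+"))
        rc = _revcomp(w)
        if rc in fwd:
            for x in plist:
                for y in fwd[rc]:
                    points.append((x, y, "-"))
    points.sort()
    return points


# ---------------------------------------------------------------------------
# masking / coverage


def _chain_and_extend(
    tarr: np.ndarray,
    qarr: np.ndarray,
    seeds: list[tuple[int, int]],  # (tpos, qpos) on one diagonal group
    k: int,
    max_divergence: float,
) -> tuple[int, int] | None:
    """Extend a diagonal seed chain into a target interval; None if too diverged."""
    diag = int(np.median([t - q for t, q in seeds]))
    on_diag = [t for t, q in seeds if abs((t - q) - diag) <= 2] or [t for t, _ in seeds]
    t_lo = min(on_diag)
    t_hi = max(on_diag) + k - 1
    nt, nq = len(tarr), len(qarr)
    lo_bound = max(0, diag)
    hi_bound = min(nt, nq + diag)
    span = np.arange(lo_bound, hi_bound)
    if span.size == 0:
        return None
    match = tarr[lo_bound:hi_bound] == qarr[lo_bound - diag : hi_bound - diag]
    left = _xdrop_extend(match, t_lo - lo_bound, -1)
    right = _xdrop_extend(match, t_hi - lo_bound, +1)
    a, b = lo_bound + left, lo_bound + right + 1
    if b - a < 50:
        return None
    divergence = 1.0 - float(match[left : right + 1].mean())
    if divergence > max_divergence:
        return None
    return a, b


def mask_coverage(
    genome: list[tuple[str, str]],
    consensus_library: list[tuple[str, str]],
    max_divergence: float = 0.20,
    k: int = 13,
    diag_tolerance: int = 15,
    chain_gap: int = 500,
) -> MaskedAnnotation:
    """Seed-and-extend masking of a genome with a consensus library.

    Alignments whose divergence (mismatches / alignment length) exceeds
    ``max_divergence`` are rejected; accepted target intervals are merged and
    coverage is reported both over total assembly length and excluding N runs.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    assembly_bp = 0
    gap_bp = 0
    for contig, tseq in genome:
        tseq = tseq.upper()
        assembly_bp += len(tseq)
        gap_bp += tseq.count("N")
        tarr = np.frombuffer(tseq.encode(), dtype="S1")
        index: dict[str, list[int]] = {}
        for i in range(len(tseq) - k + 1):
            word = tseq[i : i + k]
            if "N" not in word:
                index.setdefault(word, []).append(i)
        found: list[tuple[int, int]] = []
        for _, qseq in consensus_library:
            for q in (qseq.upper(), _revcomp(qseq.upper())):
                qarr = np.frombuffer(q.encode(), dtype="S1")
                seeds: list[tuple[int, int, int]] = []  # (diag, tpos, qpos)
                for qpos in range(len(q) - k + 1):
                    for tpos in index.get(q[qpos : qpos + k], ()):
                        seeds.append((tpos - qpos, tpos, qpos))
                if not seeds:
                    continue
                seeds.sort()
                groups: list[list[tuple[int, int]]] = []
                last_diag = None
                last_t = None
                for diag, tpos, qpos in seeds:
                    if (
                        groups
                        and last_diag is not None
                        and abs(diag - last_diag) <= diag_tolerance
                        and tpos - last_t <= chain_gap
                    ):
                        groups[-1].append((tpos, qpos))
                    else:
                        groups.append([(tpos, qpos)])
                    last_diag, last_t = diag, tpos
                for grp in groups:
                    res = _chain_and_extend(tarr, qarr, grp, k, max_divergence)
                    if res:
                        found.append(res)
        merged: list[tuple[int, int]] = []
        for a, b in sorted(found):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        intervals[contig] = merged
    masked_bp = sum(b - a for ivs in intervals.values() for a, b in ivs)
    return MaskedAnnotation(
        intervals=intervals, masked_bp=masked_bp, assembly_bp=assembly_bp, gap_bp=gap_bp
    )
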