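"""Domain annotation of consensus sequences and the fixation (n-filter) report.

Consensuses are scanned with the same translated-PSSM engine used for RT
discovery; canonical retrotransposon domain families (Gag, protease, RT,
RNaseH, integrase, Chromo) are filtered out; redundant hits against
homologous profiles are collapsed; and a domain counts as fixed in a species
only when it is detected in at least ``min_consensuses`` consensus sequences
from that species (the fixation filter, default 5).  Superfamily calls come
from the best local-alignment bit of the translated RT region against a
labeled reference library.  Motif scanners report the demethylase cofactor
motifs (HxD/E...H iron core, RxxxxxR, YNF) and K/R-rich basic patches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from ._alignment import local_aa_score
from .consensus import ConsensusRecord
from .pssm import DomainProfile, scan_profiles, six_frame_translate
from .simulate import ProfileLibrary

CANONICAL_FAMILIES = frozenset({"Gag", "protease", "RT", "RNaseH", "integrase", "Chromo"})
SUPERFAMILY_ORDER = ("Copia", "Gypsy", "DIRS", "ERV", "Caulimoviridae", "LINE")


@dataclass
class DomainHit:
    consensus_id: str
    profile: str
    family: str
    strand: str
    frame_offset: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    score: float
    species_id: str = "unknown"


@dataclass
class SuperfamilyCall:
    consensus_id: str
    label: str  # Copia/Gypsy/DIRS/ERV/Caulimoviridae/LINE/unclassified
    best_score: float
    margin: float  # to the runner-up superfamily
    ambiguous: bool = False


@dataclass
class DomainReport:
    """Species x domain-family consensus counts, filtered and unfiltered."""

    filtered: pd.DataFrame
    unfiltered: pd.DataFrame
    min_consensuses: int


def scan_domains(
    record: ConsensusRecord,
    library: ProfileLibrary | list[DomainProfile],
    threshold: float | None = None,
) -> list[DomainHit]:
    """Scan a consensus for domain profiles; merge overlapping same-family hits."""
    profiles = library.profiles if isinstance(library, ProfileLibrary) else library
    raw = scan_profiles(record.seq, list(profiles), threshold=threshold)
    raw.sort(key=lambda h: (h.family, h.nt_start, h.nt_end))
    merged: list[DomainHit] = []
    for rh in raw:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.family == rh.family
            and rh.nt_start < last.nt_end
        ):
            last.nt_end = max(last.nt_end, rh.nt_end)
            if rh.score > last.score:
                last.score = rh.score
                last.profile = rh.profile
                last.strand = rh.strand
                last.frame_offset = rh.frame_offset
                last.aa_start, last.aa_end = rh.aa_start, rh.aa_end
        else:
            merged.append(
                DomainHit(
                    consensus_id=record.consensus_id,
                    profile=rh.profile,
                    family=rh.family,
                    strand=rh.strand,
                    frame_offset=rh.frame_offset,
                    aa_start=rh.aa_start,
                    aa_end=rh.aa_end,
                    nt_start=rh.nt_start,
                    nt_end=rh.nt_end,
                    score=rh.score,
                    species_id=record.species_id,
                )
            )
    return merged


def classify_superfamily(
    record: ConsensusRecord,
    library: ProfileLibrary,
    rt_threshold: float | None = None,
    ambiguity_margin: float = 1.0,
) -> SuperfamilyCall:
    """Superfamily of a consensus from its best RT reference hit (highest score).

    The translated RT region of the consensus is aligned locally against every
    labeled reference RT; the label of the maximum wins, ties resolved toward
    the earlier label in a fixed superfamily order and flagged ambiguous.
    Consensuses without a detectable RT region are unclassified.
    """
    rt_profiles = library.family_profiles("RT")
    hits = [h for h in scan_profiles(record.seq, rt_profiles, threshold=rt_threshold)]
    if not hits:
        return SuperfamilyCall(record.consensus_id, "unclassified", 0.0, 0.0)
    best_hit = max(hits, key=lambda h: h.score)
    frames = six_frame_translate(record.seq)
    frame = next(
        f for f in frames if f.strand == best_hit.strand and f.offset == best_hit.frame_offset
    )
    query = frame.aa[best_hit.aa_start : best_hit.aa_end]
    scores: dict[str, float] = {}
    for _, superfamily, ref in library.rt_refs:
        s = local_aa_score(query, ref)
        scores[superfamily] = max(scores.get(superfamily, -np.inf), s)
    ranked = sorted(
        scores.items(), key=lambda kv: (-kv[1], SUPERFAMILY_ORDER.index(kv[0]))
    )
    best_label, best_score = ranked[0]
    margin = best_score - ranked[1][1] if len(ranked) > 1 else np.inf
    return SuperfamilyCall(
        consensus_id=record.consensus_id,
        label=best_label,
        best_score=float(best_score),
        margin=float(margin),
        ambiguous=margin < ambiguity_margin,
    )


def filter_canonical(
    hits: list[DomainHit],
    canonical_families: frozenset[str] = CANONICAL_FAMILIES,
) -> list[DomainHit]:
    """Drop hits whose profile family is one of the canonical LTR-RT domains."""
    return [h for h in hits if h.family not in canonical_families]


def collapse_profile_families(
    hits: list[DomainHit],
    family_map: dict[str, str],
) -> list[DomainHit]:
    """Collapse hits against homologous profiles to one representative per family.

    ``family_map`` maps profile label -> family representative; unmapped labels
    pass through under their own name.  Within one consensus, all hits mapping
    to the same representative collapse to the single max-score hit.
    """
    best: dict[tuple[str, str], DomainHit] = {}
    order: list[tuple[str, str]] = []
    for h in hits:
        rep = family_map.get(h.profile, h.profile)
        key = (h.consensus_id, rep)
        if key not in best:
            clone = DomainHit(**vars(h))
            clone.family = rep if h.profile in family_map else h.family
            best[key] = clone
            order.append(key)
        elif h.score > best[key].score:
            clone = DomainHit(**vars(h))
            clone.family = rep if h.profile in family_map else h.family
            best[key] = clone
    return [best[k] for k in order]


def n_filter_report(hits: list[DomainHit], min_consensuses: int = 5) -> DomainReport:
    """Count distinct consensuses per (species, domain family); apply the filter.

    The unfiltered matrix is always carried alongside so the no-filter view is
    the same code path.
    """
    if hits:
        df = pd.DataFrame(
            {
                "species": [h.species_id for h in hits],
                "family": [h.family for h in hits],
                "consensus": [h.consensus_id for h in hits],
            }
        )
        counts = (
            df.groupby(["species", "family"])["consensus"].nunique().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(dtype=int)
    filtered = counts.where(counts >= min_consensuses, 0)
    filtered = filtered.loc[:, (filtered != 0).any(axis=0)] if not filtered.empty else filtered
    filtered = filtered.loc[(filtered != 0).any(axis=1)] if not filtered.empty else filtered
    return DomainReport(filtered=filtered, unfiltered=counts, min_consensuses=min_consensuses)


# ---------------------------------------------------------------------------
# motif scanners


@dataclass
class MotifRecord:
    iron_core: tuple[int, int] | None = None  # (HxD/E start, distal H position)
    r_motif: int | None = None  # RxxxxxR start
    ynf: int | None = None
    ny_pair: tuple[int, int] | None = None  # aligned N/Y stabilizing pair
    details: dict = field(default_factory=dict)

    @property
    def all_present(self) -> bool:
        return None not in (self.iron_core, self.r_motif, self.ynf)


def check_cofactor_motifs(
    aa_seq: str,
    distal_h_span: tuple[int, int] = (30, 90),
    reference_block: str | None = None,
    reference_positions: dict[str, int] | None = None,
) -> MotifRecord:
    """Check a 2-ODD amino-acid region for the demethylase cofactor motifs.

    Reports (i) the H-x-D/E iron motif followed by a distal H within
    ``distal_h_span`` residues downstream of the motif start, (ii) RxxxxxR,
    (iii) YNF; and, when an alignment reference block with named positions is
    supplied, whether the residues aligned to the 2-OG-stabilizing N/Y pair
    are conserved.
    """
    rec = MotifRecord()
    if len(aa_seq) < 3:
        return rec
    lo, hi = distal_h_span
    for m in re.finditer(r"H.[DE]", aa_seq):
        window = aa_seq[m.start() + lo : m.start() + hi + 1]
        h_off = window.find("H")
        if h_off >= 0:
            rec.iron_core = (m.start(), m.start() + lo + h_off)
            break
    m = re.search(r"R.{5}R", aa_seq)
    if m:
        rec.r_motif = m.start()
    m = re.search(r"YNF", aa_seq)
    if m:
        rec.ynf = m.start()
    if reference_block and reference_positions:
        n_pos = reference_positions.get("N")
        y_pos = reference_positions.get("Y")
        if n_pos is not None and y_pos is not None:
            aligner = Align.PairwiseAligner(
                mode="global", match_score=1, mismatch_score=-1,
                open_gap_score=-5, extend_gap_score=-1,
            )
            aln = aligner.align(reference_block, aa_seq)[0]
            ref_to_query = {}
            for (rs, re_), (qs, qe) in zip(*aln.aligned):
                for k in range(re_ - rs):
                    ref_to_query[rs + k] = qs + k
            qn = ref_to_query.get(n_pos)
            qy = ref_to_query.get(y_pos)
            if qn is not None and qy is not None and aa_seq[qn] == "N" and aa_seq[qy] == "Y":
                rec.ny_pair = (qn, qy)
    return rec


def scan_basic_patch(
    aa_seq: str,
    window: int = 25,
    kr_fraction: float = 0.4,
) -> list[tuple[int, int]]:
    """K/R-rich intervals: merged maximal runs of windows with >= kr_fraction K/R."""
    n = len(aa_seq)
    if n == 0:
        return []
    w = min(window, n)
    is_kr = np.fromiter((c in "KR" for c in aa_seq), dtype=float, count=n)
    csum = np.concatenate([[0.0], np.cumsum(is_kr)])
    intervals: list[tuple[int, int]] = []
    for i in range(n - w + 1):
        if (csum[i + w] - csum[i]) / w >= kr_fraction:
            start, end = i, i + w
            if intervals and start <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))
    return intervals
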