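"""Synthetic genomes, TE families, profile/reference libraries and biochemical fixtures.

This module generates the inputs the discovery pipeline assumes, together with
ground-truth annotations, so every downstream stage can be tested offline:

* LTR-retrotransposon master elements with the canonical architecture
  (identical LTRs carrying short terminal inverted repeats, a primer binding
  site antisense to a host tRNA 3' end, a polypurine tract ahead of the 3'
  LTR, and stop-free ORFs embedding amino-acid domain cassettes);
* multi-copy genomes with controlled per-copy divergence, strand choice and
  assembly gaps (N runs);
* a library of amino-acid PSSMs for canonical and non-canonical domains, a
  superfamily-labeled reverse-transcriptase reference set and a small tRNA set;
* EMSA binding series following a Hill isotherm and chromatograms with
  Gaussian nucleoside peaks at fixed retention times.

Coordinates are 0-based half-open throughout; writers convert on output.
Background sequence is iid with a specified GC content so that implanted
elements are the only repetitive signal and truth stays unambiguous.
Divergence is substitution-only by default; indels are opt-in (never inside
LTRs) because LTR-pair detection tests need controllable edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .pssm import AA_ALPHABET, DomainProfile, build_profile

NT = np.array(list("ACGT"))

# codon table restricted to sense codons, for stop-free codon-level sampling
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_codon)


class SizingError(ValueError):
    """Requested element features do not fit in the requested total length."""


class PlacementError(ValueError):
    """Implanted intervals would overlap (or fall off the contig)."""


@dataclass(frozen=True)
class OrfSpec:
    orf_id: str
    aa_length: int
    cassettes: tuple[str, ...] = ()
    kr_patch: bool = False  # start the ORF with a 30-aa K/R-rich basic patch


@dataclass(frozen=True)
class ElementSpec:
    family_id: str
    total_len: int
    ltr_len: int
    orf_specs: tuple[OrfSpec, ...]
    pbs_trna: str | None = "tRNA-Arg"
    ppt: bool = True
    tir_len: int = 5
    divergence: float = 0.02
    copy_number: int = 1
    pbs_len: int = 14
    ppt_len: int = 14
    indels: bool = False

    def validate(self) -> None:
        if not 0 <= self.divergence < 0.3:
            raise ValueError("divergence must be in [0, 0.3)")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not 0 <= self.tir_len <= 10:
            raise ValueError("tir_len must be in [0, 10]")
        if self.pbs_trna is not None and not 12 <= self.pbs_len <= 18:
            raise ValueError("pbs_len must be in [12, 18]")
        if self.total_len < 2 * self.ltr_len:
            raise SizingError("total_len smaller than the two LTRs")


@dataclass(frozen=True)
class Feature:
    kind: str  # LTR5, LTR3, PBS, PPT, ORF, domain
    start: int
    end: int
    label: str | None = None

    def shift(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class GenomeSimSpec:
    species_id: str
    genome_len: int
    elements: tuple[ElementSpec, ...]
    gc: float = 0.5
    gap_runs: tuple[tuple[int, int], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class TruthCopy:
    """Ground truth for one implanted element copy (genome coordinates)."""

    species_id: str
    family_id: str
    contig: str
    start: int
    end: int
    strand: str
    features: tuple[Feature, ...]
    identity: float  # realized identity to the family master


@dataclass(frozen=True)
class ProfileLibrary:
    profiles: tuple[DomainProfile, ...]
    rt_refs: tuple[tuple[str, str, str], ...]  # (label, superfamily, aa seq)
    trnas: tuple[tuple[str, str], ...]  # (label, nt seq)

    def by_label(self, label: str) -> DomainProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise KeyError(label)

    def family_profiles(self, family: str) -> list[DomainProfile]:
        return [p for p in self.profiles if p.family == family]


# ---------------------------------------------------------------------------
# random sequence primitives


def _random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(NT[rng.choice(4, size=n, p=p)])


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _encode_orf(rng: np.random.Generator, aa_seq: str) -> str:
    """Reverse-translate by uniform sampling over sense codons, plus a stop."""
    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in aa_seq]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "".join(codons) + stop


def _mutate_aa(rng: np.random.Generator, aa_seq: str, rate: float) -> str:
    out = list(aa_seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA_ALPHABET[rng.integers(20)]
    return "".join(out)


def mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """iid substitutions at *rate*; returns (sequence, substitution count)."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        old = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != old]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode(), int(hit.size)


# ---------------------------------------------------------------------------
# element and genome generation


def generate_element(
    spec: ElementSpec,
    library: ProfileLibrary,
    seed: int,
    cassette_noise: float = 0.02,
) -> tuple[str, tuple[Feature, ...]]:
    """Build a master element sequence and its feature map (element coords).

    Layout: ``LTR5 | PBS | pad | ORF1 | pad | ... | ORFk | pad | PPT | LTR3``.
    The two LTRs are identical; each begins with a short inverted repeat
    (canonical TG...CA termini) of ``tir_len``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    # LTR with terminal inverted repeat
    t = spec.tir_len
    if t >= 2:
        tir = "TG" + _random_nt(rng, t - 2)
    else:
        tir = _random_nt(rng, t)
    core = _random_nt(rng, spec.ltr_len - 2 * t)
    ltr = tir + core + _revcomp(tir)
    if len(ltr) != spec.ltr_len:
        raise SizingError("ltr_len too small for the requested tir_len")

    # internal features
    pbs = ""
    if spec.pbs_trna is not None:
        trna = dict(library.trnas)[spec.pbs_trna]
        pbs = _revcomp(trna[-spec.pbs_len :])
    ppt = "".join("AG"[rng.integers(2)] for _ in range(spec.ppt_len)) if spec.ppt else ""

    orf_seqs: list[str] = []
    orf_feats: list[list[Feature]] = []
    for orf in spec.orf_specs:
        masters = [library.by_label(c).master for c in orf.cassettes]
        reserved = 1 + sum(len(m) for m in masters) + (30 if orf.kr_patch else 0)
        if orf.aa_length < reserved:
            raise SizingError(f"ORF {orf.orf_id}: aa_length {orf.aa_length} < cassettes {reserved}")
        free = orf.aa_length - reserved
        n_link = len(masters) + 1
        link_lens = [free // n_link] * n_link
        link_lens[-1] += free - sum(link_lens)
        aa_parts: list[str] = ["M"]
        feats: list[Feature] = []
        if orf.kr_patch:
            aa_parts.append("".join("KR"[rng.integers(2)] for _ in range(30)))
        pos = sum(len(p) for p in aa_parts)
        for cassette, master, ll in zip(orf.cassettes, masters, link_lens):
            aa_parts.append(_random_aa(rng, ll))
            pos += ll
            aa_parts.append(_mutate_aa(rng, master, cassette_noise))
            feats.append(Feature("domain", 3 * pos, 3 * (pos + len(master)), label=cassette))
            pos += len(master)
        aa_parts.append(_random_aa(rng, link_lens[-1]))
        aa_seq = "".join(aa_parts)
        assert len(aa_seq) == orf.aa_length
        orf_seqs.append(_encode_orf(rng, aa_seq))
        orf_feats.append(feats)

    internal_len = spec.total_len - 2 * spec.ltr_len
    used = len(pbs) + sum(len(s) for s in orf_seqs) + len(ppt)
    pad_total = internal_len - used
    if pad_total < 0:
        raise SizingError(
            f"features need {used + 2 * spec.ltr_len} nt but total_len is {spec.total_len}"
        )
    n_pads = len(orf_seqs) + 1
    pad_lens = [pad_total // n_pads] * n_pads
    pad_lens[-1] += pad_total - sum(pad_lens)

    parts: list[str] = [ltr]
    features: list[Feature] = [Feature("LTR5", 0, spec.ltr_len)]
    cursor = spec.ltr_len
    if pbs:
        features.append(Feature("PBS", cursor, cursor + len(pbs), label=spec.pbs_trna))
        parts.append(pbs)
        cursor += len(pbs)
    for i, orf_nt in enumerate(orf_seqs):
        pad = _random_nt(rng, pad_lens[i])
        if len(pad) >= 3:
            # in-frame stop directly ahead of the ORF start so the designed
            # ATG is the true ORF start (no silent upstream extension)
            pad = pad[:-3] + "TAA"
        parts.append(pad)
        cursor += len(pad)
        features.append(
            Feature("ORF", cursor, cursor + len(orf_nt), label=spec.orf_specs[i].orf_id)
        )
        features.extend(f.shift(cursor) for f in orf_feats[i])
        parts.append(orf_nt)
        cursor += len(orf_nt)
    pad = _random_nt(rng, pad_lens[-1])
    parts.append(pad)
    cursor += len(pad)
    if ppt:
        features.append(Feature("PPT", cursor, cursor + len(ppt)))
        parts.append(ppt)
        cursor += len(ppt)
    parts.append(ltr)
    features.append(Feature("LTR3", cursor, cursor + spec.ltr_len))
    seq = "".join(parts)
    assert len(seq) == spec.total_len
    return seq, tuple(features)


def _mutate_copy(
    master: str,
    features: tuple[Feature, ...],
    spec: ElementSpec,
    rng: np.random.Generator,
    indel_rate: float = 0.002,
) -> tuple[str, tuple[Feature, ...], float]:
    """Realize one diverged copy of a master element.

    Substitutions are iid over the whole copy.  When ``spec.indels`` is set,
    short indels (1-3 nt) are additionally applied to the internal region only
    (never inside LTRs) and feature coordinates are remapped.
    """
    seq, n_sub = mutate_nt(master, spec.divergence, rng)
    identity = 1.0 - n_sub / len(master)
    feats = features
    if spec.indels and indel_rate > 0:
        ltr5 = next(f for f in features if f.kind == "LTR5")
        ltr3 = next(f for f in features if f.kind == "LTR3")
        events = []
        pos = ltr5.end
        while pos < ltr3.start:
            if rng.random() < indel_rate:
                size = int(rng.integers(1, 4))
                kind = "del" if rng.random() < 0.5 else "ins"
                events.append((pos, kind, size))
                pos += size + 10  # keep events apart
            else:
                pos += 1
        out = []
        prev = 0
        offsets: list[tuple[int, int]] = []  # (original position, cumulative shift)
        shift = 0
        for pos, kind, size in events:
            out.append(seq[prev:pos])
            if kind == "del":
                prev = pos + size
                shift -= size
            else:
                out.append(_random_nt(rng, size))
                prev = pos
                shift += size
            offsets.append((pos, shift))
        out.append(seq[prev:])
        seq = "".join(out)

        def remap(x: int) -> int:
            s = 0
            for pos, sh in offsets:
                if pos <= x:
                    s = sh
                else:
                    break
            return x + s

        feats = tuple(replace(f, start=remap(f.start), end=remap(f.end)) for f in features)
    return seq, feats, identity


def _flip_features(feats: tuple[Feature, ...], length: int) -> tuple[Feature, ...]:
    out = []
    for f in feats:
        kind = {"LTR5": "LTR3", "LTR3": "LTR5"}.get(f.kind, f.kind)
        out.append(replace(f, kind=kind, start=length - f.end, end=length - f.start))
    return tuple(sorted(out, key=lambda f: f.start))


def generate_genome(
    spec: GenomeSimSpec,
    library: ProfileLibrary,
    masters: dict[str, tuple[str, tuple[Feature, ...]]] | None = None,
) -> tuple[list[tuple[str, str]], list[TruthCopy]]:
    """Generate one contig with implanted element copies plus ground truth.

    ``masters`` optionally supplies pre-built master sequences per family
    (used e.g. for lineages of related subfamilies); families not listed are
    generated from their :class:`ElementSpec` with a seed derived from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    contig = f"{spec.species_id}_chr1"

    copies: list[tuple[ElementSpec, str, tuple[Feature, ...]]] = []
    for i, el in enumerate(spec.elements):
        el.validate()
        if masters and el.family_id in masters:
            mseq, mfeats = masters[el.family_id]
        else:
            mseq, mfeats = generate_element(el, library, seed=int(rng.integers(2**31)))
        for _ in range(el.copy_number):
            copies.append((el, mseq, mfeats))

    total_copy_len = sum(len(m) for _, m, _ in copies)
    free = spec.genome_len - total_copy_len
    if free < 0:
        raise PlacementError("element copies exceed genome_len")
    n_slots = len(copies) + 1
    weights = rng.random(n_slots) + 0.1
    gaps = np.floor(weights / weights.sum() * free).astype(int)
    gaps[-1] += free - int(gaps.sum())

    chunks: list[str] = []
    truth: list[TruthCopy] = []
    cursor = 0
    for i, (el, mseq, mfeats) in enumerate(copies):
        chunks.append(_random_nt(rng, int(gaps[i]), spec.gc))
        cursor += int(gaps[i])
        cseq, cfeats, identity = _mutate_copy(mseq, mfeats, el, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            cseq = _revcomp(cseq)
            cfeats = _flip_features(cfeats, len(cseq))
        chunks.append(cseq)
        truth.append(
            TruthCopy(
                species_id=spec.species_id,
                family_id=el.family_id,
                contig=contig,
                start=cursor,
                end=cursor + len(cseq),
                strand=strand,
                features=tuple(f.shift(cursor) for f in cfeats),
                identity=identity,
            )
        )
        cursor += len(cseq)
    chunks.append(_random_nt(rng, int(gaps[-1]), spec.gc))
    seq = "".join(chunks)
    assert len(seq) == spec.genome_len

    if spec.gap_runs:
        arr = list(seq)
        for pos, length in spec.gap_runs:
            if pos < 0 or pos + length > spec.genome_len:
                raise PlacementError("gap run outside the genome")
            for t in truth:
                if pos < t.end and t.start < pos + length:
                    raise PlacementError("gap run overlaps an implanted element")
            arr[pos : pos + length] = "N" * length
        seq = "".join(arr)

    return [(contig, seq)], truth


# ---------------------------------------------------------------------------
# libraries


@dataclass(frozen=True)
class DomainSpec:
    label: str
    family: str
    length: int
    canonical: bool


DEFAULT_DOMAIN_SPECS: tuple[DomainSpec, ...] = (
    DomainSpec("GAG", "Gag", 120, True),
    DomainSpec("PR", "protease", 100, True),
    DomainSpec("RT_Gypsy", "RT", 200, True),
    DomainSpec("RT_Copia", "RT", 200, True),
    DomainSpec("RH", "RNaseH", 130, True),
    DomainSpec("INT", "integrase", 150, True),
    DomainSpec("Chromo", "Chromo", 60, True),
    DomainSpec("2-ODD", "2-ODD", 180, False),
    DomainSpec("PMD", "PMD", 150, False),
    DomainSpec("G-patch", "G-patch", 48, False),
    DomainSpec("AIR1", "AIR1", 60, False),
)

SUPERFAMILIES = ("Copia", "Gypsy", "DIRS", "ERV", "Caulimoviridae", "LINE")


def _odd_master(rng: np.random.Generator, length: int) -> str:
    """A 2-ODD master carrying the conserved demethylase cofactor motifs.

    The iron-binding HxD...H core, the RxxxxxR 2-OG motif and the YNF m6A
    pocket are written at fixed positions so motif scanning has a planted
    positive in every generated 2-ODD cassette.
    """
    aa = list(_random_aa(rng, length))
    aa[60:63] = list("HVD")  # HxD
    aa[120] = "H"  # distal H, 60 residues downstream
    aa[140:147] = list("RAAAAAR")  # RxxxxxR
    aa[160:163] = list("YNF")
    aa[30] = "N"
    aa[32] = "Y"  # 2-OG stabilizing N/Y pair
    return "".join(aa)


def generate_profile_library(
    domain_specs: tuple[DomainSpec, ...] = DEFAULT_DOMAIN_SPECS,
    seed: int = 0,
) -> ProfileLibrary:
    """Generate domain PSSMs, a labeled RT reference set and a tRNA set."""
    rng = np.random.default_rng(seed)
    profiles = []
    for ds in domain_specs:
        if ds.family == "2-ODD" and ds.length >= 170:
            master = _odd_master(rng, ds.length)
        else:
            master = _random_aa(rng, ds.length)
        profiles.append(build_profile(master, ds.label, ds.family, ds.canonical))

    by_label = {p.label: p for p in profiles}
    rt_refs: list[tuple[str, str, str]] = []
    for sf in SUPERFAMILIES:
        source = by_label.get(f"RT_{sf}")
        base = source.master if source is not None else _random_aa(rng, 200)
        for v in range(2):
            seq = base if v == 0 else _mutate_aa(rng, base, 0.05)
            rt_refs.append((f"RT_{sf}_{v}", sf, seq))

    trnas = []
    for label in ("tRNA-Arg", "tRNA-Met", "tRNA-Lys"):
        trnas.append((label, _random_nt(rng, 75)))
    return ProfileLibrary(tuple(profiles), tuple(rt_refs), tuple(trnas))


# ---------------------------------------------------------------------------
# canned element architectures and discovery scenarios


def gypsy_odd_spec(
    family_id: str = "GypsyODD",
    total_len: int = 12000,
    ltr_len: int = 1200,
    divergence: float = 0.02,
    copy_number: int = 6,
    dual_rnaseh: bool = True,
    with_odd: bool = True,
) -> ElementSpec:
    """An Ogre-like Gypsy element: gag-pol polyprotein plus a 2-ODD ORF."""
    pol = ("GAG", "PR", "RT_Gypsy", "RH") + (("RH",) if dual_rnaseh else ()) + ("INT",)
    orfs = [OrfSpec("ORF1", 1100, pol)]
    if with_odd:
        orfs.append(OrfSpec("ORF2", 320, ("2-ODD",), kr_patch=True))
    return ElementSpec(
        family_id=family_id,
        total_len=total_len,
        ltr_len=ltr_len,
        orf_specs=tuple(orfs),
        pbs_trna="tRNA-Arg",
        divergence=divergence,
        copy_number=copy_number,
    )


def copia_spec(
    family_id: str = "CopiaPlain",
    total_len: int = 6500,
    ltr_len: int = 400,
    divergence: float = 0.02,
    copy_number: int = 6,
) -> ElementSpec:
    """A plain Copia element (integrase ahead of RT, no extra ORF)."""
    return ElementSpec(
        family_id=family_id,
        total_len=total_len,
        ltr_len=ltr_len,
        orf_specs=(OrfSpec("ORF1", 1000, ("GAG", "PR", "INT", "RT_Copia", "RH")),),
        pbs_trna="tRNA-Met",
        divergence=divergence,
        copy_number=copy_number,
    )


def reference_element_spec() -> ElementSpec:
    """The giant Ogre-like reference element used as the worked example.

    25,510 bp total with 6,425 bp LTRs, a 2,640 aa gag-pol polyprotein with a
    dual RNase H, and a 565 aa 2-ODD ORF; PBS antisense to tRNA-Arg.
    """
    return ElementSpec(
        family_id="Gypsy_ref",
        total_len=25510,
        ltr_len=6425,
        orf_specs=(
            OrfSpec("ORF1", 2640, ("GAG", "PR", "RT_Gypsy", "RH", "RH", "INT")),
            OrfSpec("ORF2", 565, ("2-ODD",), kr_patch=True),
        ),
        pbs_trna="tRNA-Arg",
        divergence=0.0,
        copy_number=1,
    )


def _mutate_orf_codons(rng: np.random.Generator, orf_nt: str, nt_divergence: float) -> str:
    """Codon-level mutation of an ORF that never introduces stops.

    Codons (except the initial ATG and the terminal stop) are resampled to a
    random sense codon at a rate chosen so the expected nucleotide divergence
    matches ``nt_divergence`` (a random sense codon differs at ~2.2 of 3
    positions).  Models purifying selection keeping the reading frame open.
    """
    codons = [orf_nt[i : i + 3] for i in range(0, len(orf_nt) - 2, 3)]
    p = min(1.0, 3.0 * nt_divergence / 2.2)
    sense = [c for group in _CODONS.values() for c in group]
    for k in range(1, len(codons) - 1):
        if rng.random() < p:
            codons[k] = sense[rng.integers(len(sense))]
    return "".join(codons)


def make_lineage_masters(
    founder_spec: ElementSpec,
    library: ProfileLibrary,
    n_subfamilies: int,
    subfamily_divergence: float,
    seed: int,
) -> dict[str, tuple[str, tuple[Feature, ...]]]:
    """Derive related subfamily masters from a common founder element.

    Each subfamily master is the founder mutated at ``subfamily_divergence``
    (substitutions only, so all subfamily masters stay colinear and keep
    identical LTR pairs).  Inside ORFs the mutation is codon-level and
    stop-free, reflecting purifying selection on families that retained
    functional coding capacity.  Returns a mapping family_id -> master.
    """
    rng = np.random.default_rng(seed)
    founder, feats = generate_element(founder_spec, library, seed=int(rng.integers(2**31)))
    ltr5 = next(f for f in feats if f.kind == "LTR5")
    ltr3 = next(f for f in feats if f.kind == "LTR3")
    orf_feats = [f for f in feats if f.kind == "ORF"]
    masters = {}
    for i in range(n_subfamilies):
        ltr, _ = mutate_nt(founder[ltr5.start : ltr5.end], subfamily_divergence, rng)
        pieces: list[str] = []
        cursor = ltr5.end
        for orf in sorted(orf_feats, key=lambda f: f.start):
            between, _ = mutate_nt(founder[cursor : orf.start], subfamily_divergence, rng)
            pieces.append(between)
            pieces.append(
                _mutate_orf_codons(rng, founder[orf.start : orf.end], subfamily_divergence)
            )
            cursor = orf.end
        tail, _ = mutate_nt(founder[cursor : ltr3.start], subfamily_divergence, rng)
        pieces.append(tail)
        master = ltr + "".join(pieces) + ltr
        assert len(master) == len(founder)
        masters[f"{founder_spec.family_id}_{i + 1}"] = (master, feats)
    return masters


def make_discovery_scenario(
    seed: int,
    n_subfamilies: int = 5,
    copies_per_subfamily: int = 6,
    copy_divergence: float = 0.02,
    subfamily_divergence: float = 0.16,
    species_id: str = "speciesX",
) -> tuple[list[tuple[str, str]], list[TruthCopy], ProfileLibrary, GenomeSimSpec]:
    """Genome of one species carrying a 2-ODD Gypsy lineage plus a plain Copia family.

    The lineage comprises ``n_subfamilies`` related subfamilies (diverged from
    a common founder) each present in ``copies_per_subfamily`` copies, which is
    the regime in which a non-canonical domain becomes fixed: each subfamily
    yields its own consensus, so the domain is seen in ``n_subfamilies``
    consensus sequences of the species.
    """
    rng = np.random.default_rng(seed)
    library = generate_profile_library(seed=int(rng.integers(2**31)))
    founder = gypsy_odd_spec(
        family_id="GypsyODD", divergence=copy_divergence, copy_number=copies_per_subfamily
    )
    masters = make_lineage_masters(
        founder, library, n_subfamilies, subfamily_divergence, seed=int(rng.integers(2**31))
    )
    elements = [
        replace(founder, family_id=fam)
        for fam in masters
    ]
    elements.append(copia_spec(divergence=copy_divergence, copy_number=copies_per_subfamily))
    total = sum(e.total_len * e.copy_number for e in elements)
    gspec = GenomeSimSpec(
        species_id=species_id,
        genome_len=int(total * 1.4),
        elements=tuple(elements),
        seed=int(rng.integers(2**31)),
    )
    records, truth = generate_genome(gspec, library, masters=masters)
    return records, truth, library, gspec


# ---------------------------------------------------------------------------
# biochemical fixtures


@dataclass(frozen=True)
class BindingSeries:
    """EMSA lane table: protein concentrations vs free-RNA signal."""

    concentrations: tuple[float, ...]  # μM, first lane is the zero-protein lane
    free_signal: tuple[float, ...]
    total_signal: float
    true_theta: tuple[float, ...] = ()


def generate_binding_series(
    kd: float,
    hill_n: float,
    concentrations: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    total_signal: float = 1000.0,
) -> BindingSeries:
    """Fraction bound follows θ(P) = P^n / (Kd^n + P^n) plus truncated noise.

    The free-RNA signal per lane is ``total_signal * (1 - θ)``; a zero-protein
    lane (θ = 0) is always included first.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    theta = conc**hill_n / (kd**hill_n + conc**hill_n)
    if noise_sd > 0:
        theta = theta + rng.normal(0.0, noise_sd, size=theta.shape)
    eps = 1e-9
    theta = np.clip(theta, eps, 1 - eps)
    free = total_signal * (1.0 - theta)
    return BindingSeries(
        concentrations=(0.0, *map(float, conc)),
        free_signal=(total_signal, *map(float, free)),
        total_signal=total_signal,
        true_theta=(0.0, *map(float, theta)),
    )


@dataclass(frozen=True)
class Chromatogram:
    """A retention-time trace plus the discrete peak list that generated it."""

    label: str
    rt: tuple[float, ...]  # minutes, strictly increasing
    intensity: tuple[float, ...]
    peaks: tuple[tuple[str, float, float], ...]  # (nucleoside, rt center, area)


DEFAULT_PEAK_PARAMS: dict[str, tuple[float, float]] = {
    # nucleoside -> (retention time center in minutes, peak sigma in minutes)
    "G": (3.2, 0.04),
    "A": (4.5, 0.04),
    "m6A": (6.0, 0.04),
}


def generate_chromatogram(
    species_ratios: dict[str, float],
    peak_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    a_area: float = 100.0,
    g_area: float = 50.0,
    noise_sd: float = 0.0,
) -> dict[str, Chromatogram]:
    """Emit one chromatogram per sample label realizing the requested m6A/A ratio."""
    if any(r < 0 for r in species_ratios.values()):
        raise ValueError("ratios must be >= 0")
    params = dict(DEFAULT_PEAK_PARAMS if peak_params is None else peak_params)
    rng = np.random.default_rng(seed)
    rt = np.arange(0.0, 8.0, 0.002)
    out = {}
    for label, ratio in species_ratios.items():
        areas = {"G": g_area, "A": a_area, "m6A": ratio * a_area}
        trace = np.zeros_like(rt)
        peaks = []
        for nuc, (center, sigma) in params.items():
            area = areas.get(nuc, 0.0)
            if area > 0:
                trace += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                    -0.5 * ((rt - center) / sigma) ** 2
                )
            peaks.append((nuc, center, float(area)))
        if noise_sd > 0:
            trace = np.clip(trace + rng.normal(0.0, noise_sd, size=trace.shape), 0.0, None)
        out[label] = Chromatogram(
            label=label,
            rt=tuple(map(float, rt)),
            intensity=tuple(map(float, trace)),
            peaks=tuple(peaks),
        )
    return out
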