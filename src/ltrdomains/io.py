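"""Readers and writers for the package's external formats.

Internally all coordinates are 0-based half-open; GFF3/BED writers convert to
the conventions of those formats on output (GFF3 1-based inclusive, BED
0-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pssm import DomainProfile
from .rtscan import ExtendedLocus, RTHit
from .simulate import (
    BindingSeries,
    ElementSpec,
    GenomeSimSpec,
    OrfSpec,
    ProfileLibrary,
    TruthCopy,
)
from .structure import ElementModel


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def write_truth_gff3(truth: list[TruthCopy], path: str | Path) -> None:
    kind_map = {
        "LTR5": "long_terminal_repeat",
        "LTR3": "long_terminal_repeat",
        "PBS": "primer_binding_site",
        "PPT": "RR_tract",
        "ORF": "ORF",
        "domain": "polypeptide_domain",
    }
    lines = ["##gff-version 3"]
    for i, copy in enumerate(truth):
        attrs = f"ID=copy{i};family={copy.family_id};identity={copy.identity:.4f}"
        lines.append(
            "\t".join(
                [
                    copy.contig,
                    "ltrdomains",
                    "LTR_retrotransposon",
                    str(copy.start + 1),
                    str(copy.end),
                    ".",
                    copy.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for f in copy.features:
            label = f";Name={f.label}" if f.label else ""
            lines.append(
                "\t".join(
                    [
                        copy.contig,
                        "ltrdomains",
                        kind_map.get(f.kind, f.kind),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        copy.strand,
                        ".",
                        f"Parent=copy{i}{label}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_elements_gff3(models: list[ElementModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, m in enumerate(models):
        lines.append(
            "\t".join(
                [
                    m.contig,
                    "ltrdomains",
                    "LTR_retrotransposon",
                    str(m.start + 1),
                    str(m.end),
                    f"{m.ltr_identity:.4f}",
                    "+",
                    ".",
                    f"ID=element{i}",
                ]
            )
        )
        for name, (a, b) in (("ltr5", m.ltr5), ("ltr3", m.ltr3)):
            lines.append(
                "\t".join(
                    [
                        m.contig,
                        "ltrdomains",
                        "long_terminal_repeat",
                        str(a + 1),
                        str(b),
                        ".",
                        "+",
                        ".",
                        f"Parent=element{i};Name={name}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def element_to_json(m: ElementModel) -> dict:
    return {
        "contig": m.contig,
        "start": m.start,
        "end": m.end,
        "length": m.length,
        "ltr5": list(m.ltr5),
        "ltr3": list(m.ltr3),
        "ltr_len": m.ltr_len,
        "ltr_identity": m.ltr_identity,
        "tir_len": m.tir_len,
        "pbs": None
        if m.pbs is None
        else {"trna": m.pbs.trna, "start": m.pbs.start, "end": m.pbs.end},
        "ppt": None
        if m.ppt is None
        else {"start": m.ppt.start, "end": m.ppt.end, "purine_fraction": m.ppt.purine_fraction},
        "orfs": [
            {"start": o.start, "end": o.end, "strand": o.strand, "aa_length": o.aa_length}
            for o in m.orfs
        ],
        "rnaseh_copy_count": m.rnaseh_copy_count,
    }


# ---------------------------------------------------------------------------
# BED


def write_hits_bed(hits: list[RTHit], path: str | Path) -> None:
    """BED6; the score column is bits x 100, integer."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.contig,
                    str(h.start),
                    str(h.end),
                    h.best_profile,
                    str(int(round(h.best_score * 100))),
                    h.strand,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_loci_fasta(loci: list[ExtendedLocus], path: str | Path) -> None:
    write_fasta([(l.locus_id, l.seq) for l in loci], path)


# ---------------------------------------------------------------------------
# profile library serialization


def save_library(library: ProfileLibrary, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    payload = {
        "profiles": [
            {
                "label": p.label,
                "family": p.family,
                "canonical": p.canonical,
                "master": p.master,
                "matrix": p.matrix.tolist(),
            }
            for p in library.profiles
        ],
        "rt_refs": [list(r) for r in library.rt_refs],
        "trnas": [list(t) for t in library.trnas],
    }
    (d / "library.json").write_text(json.dumps(payload))


def load_library(directory: str | Path) -> ProfileLibrary:
    payload = json.loads((Path(directory) / "library.json").read_text())
    profiles = tuple(
        DomainProfile(
            label=p["label"],
            family=p["family"],
            canonical=p["canonical"],
            master=p["master"],
            matrix=np.array(p["matrix"]),
        )
        for p in payload["profiles"]
    )
    rt_refs = tuple(tuple(r) for r in payload["rt_refs"])
    trnas = tuple(tuple(t) for t in payload["trnas"])
    return ProfileLibrary(profiles, rt_refs, trnas)


# ---------------------------------------------------------------------------
# YAML genome specs


def spec_to_yaml(spec: GenomeSimSpec, path: str | Path) -> None:
    doc = {
        "species_id": spec.species_id,
        "genome_len": spec.genome_len,
        "gc": spec.gc,
        "seed": spec.seed,
        "gap_runs": [list(g) for g in spec.gap_runs],
        "elements": [
            {
                "family_id": e.family_id,
                "total_len": e.total_len,
                "ltr_len": e.ltr_len,
                "pbs_trna": e.pbs_trna,
                "ppt": e.ppt,
                "tir_len": e.tir_len,
                "divergence": e.divergence,
                "copy_number": e.copy_number,
                "orfs": [
                    {
                        "orf_id": o.orf_id,
                        "aa_length": o.aa_length,
                        "cassettes": list(o.cassettes),
                        "kr_patch": o.kr_patch,
                    }
                    for o in e.orf_specs
                ],
            }
            for e in spec.elements
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> GenomeSimSpec:
    doc = yaml.safe_load(Path(path).read_text())
    elements = tuple(
        ElementSpec(
            family_id=e["family_id"],
            total_len=e["total_len"],
            ltr_len=e["ltr_len"],
            orf_specs=tuple(
                OrfSpec(
                    o["orf_id"],
                    o["aa_length"],
                    tuple(o.get("cassettes", ())),
                    o.get("kr_patch", False),
                )
                for o in e.get("orfs", [])
            ),
            pbs_trna=e.get("pbs_trna", "tRNA-Arg"),
            ppt=e.get("ppt", True),
            tir_len=e.get("tir_len", 5),
            divergence=e.get("divergence", 0.02),
            copy_number=e.get("copy_number", 1),
        )
        for e in doc.get("elements", [])
    )
    return GenomeSimSpec(
        species_id=doc["species_id"],
        genome_len=doc["genome_len"],
        elements=elements,
        gc=doc.get("gc", 0.5),
        gap_runs=tuple(tuple(g) for g in doc.get("gap_runs", [])),
        seed=doc.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# biochem CSV

def read_binding_series_csv(
    path: str | Path,
    mw_kda: float | None = None,
    volume_ul: float = 10.0,
) -> BindingSeries:
    """Lane table with a ``free_signal`` column and either ``concentration_um``
    or ``mass_ng`` (the form EMSA experiments report; converting requires the
    protein molecular weight ``mw_kda`` and the binding volume).

    The zero-concentration lane supplies the total signal.
    """
    df = pd.read_csv(path)
    if "free_signal" not in df.columns:
        raise ValueError("expected a free_signal column")
    if "concentration_um" not in df.columns:
        if "mass_ng" not in df.columns:
            raise ValueError("expected a concentration_um or mass_ng column")
        if mw_kda is None:
            raise ValueError("mass_ng lanes require the protein molecular weight")
        df = df.assign(concentration_um=df["mass_ng"] / (mw_kda * volume_ul))
    zero = df[df["concentration_um"] == 0]
    if zero.empty:
        raise ValueError("a zero-protein lane is required")
    total = float(zero["free_signal"].iloc[0])
    return BindingSeries(
        concentrations=tuple(float(c) for c in df["concentration_um"]),
        free_signal=tuple(float(s) for s in df["free_signal"]),
        total_signal=total,
    )


def read_peaks_csv(path: str | Path) -> list[tuple[str, float, float]]:
    """Peak list with columns ``nucleoside``, ``rt``, ``area``."""
    df = pd.read_csv(path)
    return [
        (str(r.nucleoside), float(r.rt), float(r.area)) for r in df.itertuples(index=False)
    ]
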