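"""Readers and writers for the package's standard exchange formats.

Parts registries travel as FASTA with an optional tab-separated metadata
sidecar; assembled constructs as GenBank records (one CDS per cistron,
misc_feature entries for every cassette sub-domain, an RBS feature for the
Shine-Dalgarno sequence) or plain FASTA; candidate sets as FASTA plus a
tab-separated score/flag table; junction reports as tab-separated tables.

GenBank coordinates are 1-based inclusive; the conversion from the
internal 0-based half-open convention happens entirely at this boundary
(Biopython's ``SimpleLocation`` carries the internal convention and
renders the GenBank one).  Records are written with a fixed date stamp so
identical designs serialize byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .assembly import Junction, JunctionReport, OperonDesign, Part
from .design import Candidate
from .seqcore import NucSeq, Region, SeqValidationError, to_rna

__all__ = [
    "read_parts",
    "write_parts",
    "write_construct",
    "read_construct",
    "write_candidates_fasta",
    "write_score_table",
    "write_junction_table",
]

#: Fixed GenBank LOCUS date so outputs are reproducible byte-for-byte.
_RECORD_DATE = "01-JAN-2024"

_INT_METADATA_KEYS = {"stem_len", "loop_len"}


def _parse_metadata_tokens(tokens: Sequence[str]) -> Dict[str, object]:
    meta: Dict[str, object] = {}
    for tok in tokens:
        if "=" not in tok:
            continue
        key, value = tok.split("=", 1)
        meta[key] = int(value) if key in _INT_METADATA_KEYS else value
    return meta


def read_parts(
    path: str | Path, metadata_path: str | Path | None = None
) -> List[Part]:
    """Read a parts registry from FASTA (plus optional sidecar TSV).

    The part role comes from a ``role=...`` token in the FASTA description
    or from the sidecar's ``role`` column; further ``key=value`` tokens
    (or sidecar columns) become part metadata.  T residues are transcribed
    to U on the way in.
    """
    sidecar: Dict[str, Dict[str, object]] = {}
    if metadata_path is not None:
        df = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "name" not in df.columns:
            raise SeqValidationError("metadata sidecar needs a 'name' column")
        for _, row in df.iterrows():
            entry = {
                k: (int(v) if k in _INT_METADATA_KEYS else v)
                for k, v in row.items()
                if k != "name" and pd.notna(v)
            }
            sidecar[row["name"]] = entry
    parts: List[Part] = []
    for lineno_guard, record in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            seq = to_rna(str(record.seq))
        except SeqValidationError as exc:
            raise SeqValidationError(
                f"{path}: record {record.id!r}: {exc}"
            ) from None
        tokens = record.description.split()[1:]
        meta = _parse_metadata_tokens(tokens)
        meta.update(sidecar.get(record.id, {}))
        role = str(meta.pop("role", "orf"))
        parts.append(Part(name=record.id, role=role, sequence=seq, metadata=meta))
    if not parts:
        raise SeqValidationError(f"{path}: no FASTA records found")
    return parts


def write_parts(
    parts: Sequence[Part],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a parts registry as FASTA (role inline) + optional TSV sidecar."""
    with open(path, "w") as fh:
        for part in parts:
            fh.write(f">{part.name} role={part.role}\n{part.sequence}\n")
    if metadata_path is not None:
        keys = sorted({k for p in parts for k in p.metadata})
        rows = [
            {"name": p.name, "role": p.role,
             **{k: p.metadata.get(k, "") for k in keys}}
            for p in parts
        ]
        pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def _region_to_feature(region: Region) -> SeqFeature:
    kind, _, name = region.label.partition(":")
    if kind == "orf":
        ftype = "CDS"
        qualifiers = {"gene": [name], "codon_start": ["1"],
                      "label": [region.label]}
    elif kind == "rbs":
        ftype = "RBS"
        qualifiers = {"label": [region.label]}
    else:
        ftype = "misc_feature"
        qualifiers = {"label": [region.label]}
    return SeqFeature(
        SimpleLocation(region.start, region.end, strand=1),
        type=ftype,
        qualifiers=qualifiers,
    )


def _design_to_record(design: OperonDesign, name: str) -> SeqRecord:
    record = SeqRecord(
        Seq(str(design.transcript)),
        id=name,
        name=name[:16],
        description="synTCE operon transcript",
    )
    record.annotations["molecule_type"] = "RNA"
    record.annotations["topology"] = "linear"
    record.annotations["date"] = _RECORD_DATE
    for region in design.annotations:
        record.features.append(_region_to_feature(region))
    for junction in design.junctions:
        feature = SeqFeature(
            SimpleLocation(junction.stop_region.start,
                           junction.start_region.end, strand=1),
            type="misc_feature",
            qualifiers={
                "label": [f"junction:{junction.syntce_name}"],
                "note": [
                    f"stem_len={junction.stem_len} "
                    f"loop_len={junction.loop_len} "
                    f"cassette={junction.cassette_region.start}.."
                    f"{junction.cassette_region.end}"
                ],
            },
        )
        record.features.append(feature)
    return record


def write_construct(
    design: OperonDesign,
    path: str | Path,
    fmt: str = "genbank",
    name: str = "construct",
) -> None:
    """Serialize an assembled operon as GenBank (annotated) or FASTA."""
    if fmt == "fasta":
        with open(path, "w") as fh:
            fh.write(f">{name}\n{design.transcript}\n")
        return
    if fmt != "genbank":
        raise SeqValidationError(f"unsupported construct format {fmt!r}")
    record = _design_to_record(design, name)
    SeqIO.write([record], str(path), "genbank")


def read_construct(path: str | Path) -> OperonDesign:
    """Re-load a GenBank construct into an annotated design.

    The original part list is not recoverable from a flat record; the
    returned design carries the transcript, all annotation regions and the
    reconstructed junction records, which is what validation and scoring
    need.
    """
    record = SeqIO.read(str(path), "genbank")
    transcript = to_rna(str(record.seq))
    annotations: List[Region] = []
    junction_meta: List[Tuple[str, int, int, int, int]] = []
    subdomains: Dict[str, Dict[str, Region]] = {}
    for feature in record.features:
        label = feature.qualifiers.get("label", [""])[0]
        if not label:
            continue
        start = int(feature.location.start)
        end = int(feature.location.end)
        kind, _, name = label.partition(":")
        if kind == "junction":
            note = feature.qualifiers.get("note", [""])[0]
            meta = _parse_metadata_tokens(note.split())
            cas = str(meta.get("cassette", "0..0"))
            cas_start, cas_end = (int(x) for x in cas.split(".."))
            junction_meta.append(
                (name, int(meta["stem_len"]), int(meta["loop_len"]),
                 cas_start, cas_end)
            )
            continue
        frame = start % 3 if kind == "orf" else 0
        annotations.append(Region(start, end, frame=frame, label=label))
        if kind in ("stem5", "loop", "stem3", "rbs", "uraug"):
            subdomains.setdefault(name, {})[kind] = Region(start, end, label=label)
    junctions: List[Junction] = []
    for index, (name, stem_len, loop_len, cas_start, cas_end) in enumerate(
        sorted(junction_meta, key=lambda t: t[3])
    ):
        stop_start = cas_start + 2 * stem_len + loop_len
        upstream_orfs = [
            r for r in annotations
            if r.label.startswith("orf:") and r.end == stop_start + 3
        ]
        upstream_run = (
            stop_start + 3 - upstream_orfs[0].start if upstream_orfs else 0
        )
        junctions.append(
            Junction(
                index=index,
                syntce_name=name,
                cassette_region=Region(cas_start, cas_end),
                stop_region=Region(stop_start, stop_start + 3,
                                   frame=stop_start % 3, label="stop"),
                start_region=Region(stop_start + 2, stop_start + 5,
                                    frame=(stop_start + 2) % 3, label="start"),
                stem_len=stem_len,
                loop_len=loop_len,
                upstream_run_nt=upstream_run,
            )
        )
    return OperonDesign(
        transcript=transcript,
        annotations=sorted(annotations, key=lambda r: (r.start, r.end, r.label)),
        junctions=junctions,
        parts=(),
    )


def write_candidates_fasta(
    candidates: Sequence[Candidate], path: str | Path
) -> None:
    """Ranked candidate cassettes as FASTA; the header carries provenance
    (seed, draw index), pass/fail and the headline scores."""
    with open(path, "w") as fh:
        for rank, c in enumerate(candidates):
            seed, draw = c.provenance
            fh.write(
                f">syntce_{rank:04d} seed={seed} draw={draw} "
                f"pass={'yes' if c.passes else 'no'} "
                f"designed_dG={c.structure.designed_dG:.2f} "
                f"rbs_total={c.rbs_score.total:.2f}\n{c.cassette}\n"
            )


def write_score_table(
    candidates: Sequence[Candidate], path: str | Path
) -> None:
    """Per-candidate score/flag table (tab-separated)."""
    rows = []
    for rank, c in enumerate(candidates):
        row = {
            "rank": rank,
            "draw_index": c.draw_index,
            "seed": c.spec.seed,
            "cassette": str(c.cassette),
            "stem5": c.stem5,
            "stem_dG": round(c.stem_dG, 4),
            "designed_dG": round(c.structure.designed_dG, 4),
            "best_alt_dG": (round(c.structure.best_alt_dG, 4)
                            if c.structure.best_alt_dG != float("inf") else ""),
            "rbs_total": round(c.rbs_score.total, 4),
            "rbs_dG_rRNA_mRNA": round(c.rbs_score.dG_rRNA_mRNA, 4),
            "rbs_dG_spacing": round(c.rbs_score.dG_spacing, 4),
            "local_structure": round(c.local_structure, 4),
            "passes": c.passes,
        }
        for flag, ok in c.flags.items():
            row[f"flag_{flag}"] = ok
            row[f"reason_{flag}"] = c.reasons.get(flag, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_junction_table(
    reports: Sequence[JunctionReport], path: str | Path
) -> None:
    """Per-junction validation table (tab-separated)."""
    rows = [
        {
            "junction": i,
            "intergenic_distance": r.intergenic_distance,
            "distance_class": r.distance_class,
            "rbs_total": round(r.rbs_score.total, 4),
            "rbs_dG_rRNA_mRNA": round(r.rbs_score.dG_rRNA_mRNA, 4),
            "rbs_dG_spacing": round(r.rbs_score.dG_spacing, 4),
            "structure_pass": r.structure_check.passed,
            "designed_dG": round(r.structure_check.designed_dG, 4)
            if r.structure_check.designed_dG != float("inf") else "",
            "warnings": "; ".join(r.warnings),
        }
        for i, r in enumerate(reports)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
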