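"""Compilation of parts into annotated multi-output operon transcripts.

Parts (opaque riboregulator switches, ORFs, translated linkers and synTCE
cassettes) are concatenated 5'->3' into one transcript.  At every synTCE
the upstream ORF's stop codon is spliced out, the ribosome reads through
the (translated) linker and cassette prefix, and terminates at the
cassette's junction stop codon; the downstream ORF's start codon is the
AUG overlapping that stop by one nucleotide (URAUG), so the downstream
frame is ``junction_frame(upstream_frame)``.

Every junction can be validated for intergenic distance, RBS strength at
the coupled start codon and hairpin dominance; long upstream runs trigger
graded warnings because coupling efficiency decays for cistrons beyond
~1 kb and ON/OFF states converge beyond ~3 kb.

Ribocomputing gate layouts (OR / AND / NAND / NIMPLY) are emitted as part
chains with a truth-table stub recording the expected qualitative output
per input combination; switch internals are not modeled, only frame and
concatenation legality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

from .config import DesignConfig, default_config
from .design import Candidate, DesignError
from .seqcore import (
    NucSeq,
    Region,
    STOP_CODONS,
    SeqValidationError,
    find_overlap_motif,
    junction_frame,
    scan_stop_codons,
    to_rna,
)
from .thermo import (
    EnergyModel,
    RBSScore,
    StructureCheck,
    _rbs_at,
    default_energy_model,
    hairpin_structure_check,
)

__all__ = [
    "Part",
    "OperonDesign",
    "Junction",
    "JunctionReport",
    "LayoutError",
    "part_from_candidate",
    "assemble_operon",
    "validate_junction",
    "validate_operon",
    "distance_class",
    "gate_layout",
    "scan_internal_rbs",
]

PART_ROLES = ("switch", "orf", "linker", "syntce", "output_tag")

#: Upstream-run lengths (nt) at which coupling-decay warnings fire.
LONG_RUN_WARN_NT = 1000
CONVERGED_WARN_NT = 3000


class LayoutError(DesignError):
    """Illegal part order or gate configuration."""


@dataclass(frozen=True)
class Part:
    """A named construct part with a validated sequence.

    ORF parts must begin with AUG, have length divisible by 3, contain no
    internal in-frame stop and end with a stop codon.  Switches are
    opaque: only their length matters to the assembler.  synTCE parts
    carry ``stem_len`` and ``loop_len`` metadata so junctions can be
    re-validated.
    """

    name: str
    role: str
    sequence: NucSeq
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in PART_ROLES:
            raise SeqValidationError(
                f"part {self.name!r}: unknown role {self.role!r}"
            )
        if isinstance(self.sequence, str):
            object.__setattr__(self, "sequence", to_rna(self.sequence))
        s = str(self.sequence)
        if self.role == "orf":
            if not s.startswith("AUG"):
                raise SeqValidationError(f"ORF {self.name!r} must begin with AUG")
            if len(s) % 3 != 0:
                raise SeqValidationError(
                    f"ORF {self.name!r} length {len(s)} is not a multiple of 3"
                )
            if s[-3:] not in STOP_CODONS:
                raise SeqValidationError(
                    f"ORF {self.name!r} must end with a stop codon"
                )
            internal = [p for p in scan_stop_codons(s, 0) if p < len(s) - 3]
            if internal:
                raise SeqValidationError(
                    f"ORF {self.name!r} has internal in-frame stop(s) at {internal}"
                )
        if self.role == "syntce":
            for key in ("stem_len", "loop_len"):
                if key not in self.metadata:
                    raise SeqValidationError(
                        f"syntce part {self.name!r} requires metadata {key!r}"
                    )


def part_from_candidate(candidate: Candidate, name: str) -> Part:
    """Wrap a designed cassette as an assembly part."""
    spec = candidate.spec
    return Part(
        name=name,
        role="syntce",
        sequence=candidate.cassette,
        metadata={
            "stem_len": spec.stem_len,
            "loop_len": len(spec.loop_seq),
            "rbs": spec.rbs,
            "provenance": candidate.provenance,
        },
    )


@dataclass(frozen=True)
class Junction:
    """Structural record of one coupling junction on the transcript."""

    index: int
    syntce_name: str
    cassette_region: Region  # full cassette, transcript coordinates
    stop_region: Region
    start_region: Region
    stem_len: int
    loop_len: int
    upstream_run_nt: int  # translated nt from upstream cistron AUG to stop end


@dataclass(frozen=True)
class JunctionReport:
    """Validation result for one junction."""

    intergenic_distance: int
    distance_class: str
    rbs_score: RBSScore
    structure_check: StructureCheck
    warnings: Tuple[str, ...] = ()


@dataclass
class OperonDesign:
    """An assembled, annotated multi-output transcript.

    ORF annotations cover the full translated cistron — from the start
    codon through every translated linker/cassette residue up to and
    including the terminating stop codon.
    """

    transcript: NucSeq
    annotations: List[Region]
    junctions: List[Junction]
    parts: Tuple[Part, ...]
    stoichiometry_plan: Dict[str, float] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    def orf_regions(self) -> List[Region]:
        return [r for r in self.annotations if r.label.startswith("orf:")]


def _parse_layout(parts: Sequence[Part]):
    """Split a part list into (switches, first orf, [(linker?, syntce, orf)...])."""
    parts = list(parts)
    i = 0
    switches = []
    while i < len(parts) and parts[i].role == "switch":
        switches.append(parts[i])
        i += 1
    if i >= len(parts) or parts[i].role != "orf":
        raise LayoutError(
            "layout error: expected an ORF after the (optional) switch modules"
        )
    first_orf = parts[i]
    i += 1
    groups = []
    while i < len(parts):
        linker = None
        if parts[i].role == "linker":
            linker = parts[i]
            i += 1
            if i >= len(parts):
                raise LayoutError("layout error: trailing linker without synTCE")
        if parts[i].role != "syntce":
            raise LayoutError(
                f"layout error: part {parts[i].name!r} (role {parts[i].role}) "
                "where a synTCE is required; consecutive ORFs must be joined "
                "by a coupling element"
            )
        syntce = parts[i]
        i += 1
        if i >= len(parts) or parts[i].role != "orf":
            raise LayoutError(
                f"layout error: synTCE {syntce.name!r} must be followed by an ORF"
            )
        groups.append((linker, syntce, parts[i]))
        i += 1
    return switches, first_orf, groups


def _syntce_annotations(
    cassette: str, stem_len: int, loop_len: int, rbs: str, name: str, offset: int
) -> List[Region]:
    regions = []
    if stem_len:
        regions.append(Region(offset, offset + stem_len, label=f"stem5:{name}"))
        regions.append(
            Region(offset + stem_len + loop_len,
                   offset + 2 * stem_len + loop_len, label=f"stem3:{name}")
        )
    regions.append(
        Region(offset + stem_len, offset + stem_len + loop_len,
               label=f"loop:{name}")
    )
    if rbs:
        loop = cassette[stem_len:stem_len + loop_len]
        off = loop.find(rbs)
        if off >= 0:
            regions.append(
                Region(offset + stem_len + off,
                       offset + stem_len + off + len(rbs), label=f"rbs:{name}")
            )
    junction = offset + 2 * stem_len + loop_len
    regions.append(Region(junction, junction + 5, label=f"uraug:{name}"))
    return regions


def assemble_operon(parts: Sequence[Part]) -> OperonDesign:
    """Concatenate parts into an annotated transcript.

    Grammar: ``switch* orf (linker? syntce orf)*``.  A three-output chain
    (orf-syntce-orf-syntce-orf) assembles the same way junction by
    junction, which makes chaining associative: extending an assembled
    design with a further (syntce, orf) pair yields the same transcript as
    assembling the full list at once.
    """
    switches, first_orf, groups = _parse_layout(parts)
    seq: List[str] = []
    annotations: List[Region] = []
    junctions: List[Junction] = []
    pos = 0
    for sw in switches:
        s = str(sw.sequence)
        seq.append(s)
        annotations.append(Region(pos, pos + len(s), label=f"switch:{sw.name}"))
        pos += len(s)

    # current cistron state: transcript position of its AUG, its name, and
    # the not-yet-emitted body (which still ends with its own stop codon)
    cistron_start = pos
    cistron_name = first_orf.name
    body = str(first_orf.sequence)

    for linker, syntce, next_orf in groups:
        # emit the upstream cistron body minus its stop codon
        emitted = body[:-3]
        seq.append(emitted)
        pos += len(emitted)
        if linker is not None:
            ls = str(linker.sequence)
            if len(ls) % 3 != 0 or scan_stop_codons(ls, 0):
                raise LayoutError(
                    f"frame error: linker {linker.name!r} is translated up to "
                    "the junction and must be stop-free with length a "
                    "multiple of 3"
                )
            seq.append(ls)
            annotations.append(
                Region(pos, pos + len(ls), label=f"linker:{linker.name}")
            )
            pos += len(ls)
        stem_len = int(syntce.metadata["stem_len"])
        loop_len = int(syntce.metadata["loop_len"])
        cas = str(syntce.sequence)
        junction_local = 2 * stem_len + loop_len
        if cas[junction_local:junction_local + 2] + cas[junction_local + 2] \
                not in STOP_CODONS:
            raise LayoutError(
                f"synTCE {syntce.name!r}: no stop codon at cassette "
                f"position {junction_local}"
            )
        upstream_frame = cistron_start % 3
        stop_abs = pos + junction_local
        if stop_abs % 3 != upstream_frame:
            raise LayoutError(
                f"frame error at junction {len(junctions)} "
                f"({syntce.name!r}): junction stop codon is out of frame "
                "with the upstream ORF"
            )
        seq.append(cas)
        annotations.append(
            Region(pos, pos + len(cas), label=f"syntce:{syntce.name}")
        )
        annotations.extend(
            _syntce_annotations(cas, stem_len, loop_len,
                                str(syntce.metadata.get("rbs", "")),
                                syntce.name, pos)
        )
        start_abs = stop_abs + 2
        junctions.append(
            Junction(
                index=len(junctions),
                syntce_name=syntce.name,
                cassette_region=Region(pos, pos + len(cas)),
                stop_region=Region(stop_abs, stop_abs + 3,
                                   frame=stop_abs % 3, label="stop"),
                start_region=Region(start_abs, start_abs + 3,
                                    frame=start_abs % 3, label="start"),
                stem_len=stem_len,
                loop_len=loop_len,
                upstream_run_nt=stop_abs + 3 - cistron_start,
            )
        )
        # close the upstream cistron annotation at its junction stop
        annotations.append(
            Region(cistron_start, stop_abs + 3, frame=cistron_start % 3,
                   label=f"orf:{cistron_name}")
        )
        assert start_abs % 3 == junction_frame(upstream_frame)
        pos += len(cas)
        # the next cistron's AUG is the cassette's trailing AUG
        cistron_start = start_abs
        cistron_name = next_orf.name
        body = str(next_orf.sequence)[3:]

    seq.append(body)
    pos += len(body)
    annotations.append(
        Region(cistron_start, pos, frame=cistron_start % 3,
               label=f"orf:{cistron_name}")
    )
    design = OperonDesign(
        transcript=NucSeq("".join(seq)),
        annotations=sorted(annotations, key=lambda r: (r.start, r.end, r.label)),
        junctions=junctions,
        parts=tuple(parts),
    )
    _revalidate(design)
    return design


def _revalidate(design: OperonDesign) -> None:
    """Re-parse the assembled transcript.

    Every annotated cistron must start with AUG, read stop-free in its
    recorded frame, and end at a stop codon; every junction's URAUG must
    be present at its annotated position.
    """
    s = str(design.transcript)
    for region in design.orf_regions():
        sub = s[region.start:region.end]
        if not sub.startswith("AUG"):
            raise LayoutError(
                f"re-validation failed: {region.label} does not start with AUG"
            )
        if len(sub) % 3 != 0:
            raise LayoutError(
                f"re-validation failed: {region.label} length {len(sub)} is "
                "not a multiple of 3"
            )
        if sub[-3:] not in STOP_CODONS:
            raise LayoutError(
                f"re-validation failed: {region.label} does not end at a stop"
            )
        premature = [p for p in scan_stop_codons(sub, 0) if p < len(sub) - 3]
        if premature:
            raise LayoutError(
                f"re-validation failed: {region.label} has in-frame stop(s) "
                f"at cistron offset(s) {premature}"
            )
    for junction in design.junctions:
        p = junction.stop_region.start
        if find_overlap_motif(s[p:p + 5]) != [0]:
            raise LayoutError(
                f"re-validation failed: junction {junction.index} has no "
                "URAUG at its annotated position"
            )


def distance_class(intergenic_distance: int) -> str:
    """Qualitative coupling-efficiency class by stop-to-start distance.

    -1..5 nt is the highly effective range; beyond it the dynamic range
    degrades gradually (6..14: "degrading") until coupling is poor (>= 15).
    """
    if intergenic_distance < -1:
        raise SeqValidationError(
            f"intergenic distance cannot be below -1, got {intergenic_distance}"
        )
    if intergenic_distance <= 5:
        return "optimal"
    if intergenic_distance <= 14:
        return "degrading"
    return "poor"


def validate_junction(
    design: OperonDesign,
    junction_index: int,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> JunctionReport:
    """Compute the full validation report for one junction."""
    model = model or default_energy_model()
    config = config or default_config()
    try:
        junction = design.junctions[junction_index]
    except IndexError:
        raise LayoutError(
            f"no junction {junction_index}; design has {len(design.junctions)}"
        ) from None
    s = str(design.transcript)
    d = junction.start_region.start - (junction.stop_region.end - 1) - 1
    rbs = _rbs_at(s, junction.start_region.start, config.anti_sd, model, config)
    window_start = junction.cassette_region.start
    hairpin_window = s[
        window_start:window_start + 2 * junction.stem_len + junction.loop_len
    ]
    rbs_regions = [
        r for r in design.annotations
        if r.label == f"rbs:{junction.syntce_name}"
    ]
    rbs_local = (
        Region(rbs_regions[0].start - window_start,
               rbs_regions[0].end - window_start)
        if rbs_regions else None
    )
    structure = hairpin_structure_check(
        hairpin_window, junction.stem_len, junction.loop_len, model, config,
        rbs=rbs_local,
    )
    warnings: List[str] = []
    if junction.upstream_run_nt > CONVERGED_WARN_NT:
        warnings.append(
            f"upstream cistron run of {junction.upstream_run_nt} nt exceeds "
            f"{CONVERGED_WARN_NT} nt: ON/OFF states expected to have converged"
        )
    elif junction.upstream_run_nt > LONG_RUN_WARN_NT:
        warnings.append(
            f"upstream cistron run of {junction.upstream_run_nt} nt exceeds "
            f"{LONG_RUN_WARN_NT} nt: coupling dynamic range decays"
        )
    return JunctionReport(
        intergenic_distance=d,
        distance_class=distance_class(d),
        rbs_score=rbs,
        structure_check=structure,
        warnings=tuple(warnings),
    )


def validate_operon(
    design: OperonDesign,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> List[JunctionReport]:
    """Validate every junction of an assembled operon."""
    return [
        validate_junction(design, i, model, config)
        for i in range(len(design.junctions))
    ]


_GATES = ("OR", "AND", "NAND", "NIMPLY")


def _truth_table(gate: str, inputs: List[str]) -> Dict[Tuple[str, ...], str]:
    table: Dict[Tuple[str, ...], str] = {}
    subsets: List[Tuple[str, ...]] = [()]
    for r in range(1, len(inputs) + 1):
        subsets.extend(tuple(c) for c in combinations(inputs, r))
    for present in subsets:
        if gate == "OR":
            on = len(present) > 0
        elif gate == "AND":
            on = set(present) == set(inputs)
        elif gate == "NAND":
            on = set(present) != set(inputs)
        else:  # NIMPLY: first input AND NOT second
            on = inputs[0] in present and inputs[1] not in present
        table[present] = "ON" if on else "OFF"
    return table


def gate_layout(
    gate: str,
    switch_parts: Sequence[Part],
    output_parts: Sequence[Part],
    syntce_parts: Optional[Sequence[Part]] = None,
) -> OperonDesign:
    """Emit a ribocomputing gate layout as an assembled operon.

    OR and NAND gates concatenate 2-6 switch (or three-way-junction
    repressor) modules in one reading frame upstream of the outputs; AND
    and NIMPLY use a single switch whose trigger is split (or antagonized
    by an antisense input), with the two input names carried in switch
    metadata ``inputs``.  Multi-output gates chain outputs with synTCEs;
    if none are supplied, default-architecture cassettes are designed
    deterministically.  A truth-table stub with the expected qualitative
    ON/OFF state per input combination is recorded in design metadata.
    """
    gate = gate.upper()
    if gate not in _GATES:
        raise LayoutError(f"unknown gate type {gate!r}; expected one of {_GATES}")
    switch_parts = list(switch_parts)
    output_parts = list(output_parts)
    if not output_parts:
        raise LayoutError("at least one output ORF is required")
    if gate in ("OR", "NAND"):
        if not 2 <= len(switch_parts) <= 6:
            raise LayoutError(
                f"{gate} gate supports 2-6 switch modules (demonstrated up "
                f"to six); got {len(switch_parts)}"
            )
        inputs = [str(p.metadata.get("trigger", p.name)) for p in switch_parts]
    else:
        if len(switch_parts) != 1:
            raise LayoutError(f"{gate} gate takes exactly one switch part")
        meta = switch_parts[0].metadata
        if "inputs" not in meta or len(meta["inputs"]) != 2:
            raise LayoutError(
                f"{gate} gate requires switch metadata 'inputs' naming the "
                "two trigger domains"
            )
        inputs = [str(x) for x in meta["inputs"]]
    for p in switch_parts:
        if len(p.sequence) % 3 != 0:
            raise LayoutError(
                f"frame error: switch module {p.name!r} length "
                f"{len(p.sequence)} breaks reading-frame continuity across "
                "concatenated modules (must be a multiple of 3)"
            )
    n_needed = len(output_parts) - 1
    if syntce_parts is None:
        if n_needed:
            from .design import SynTCESpec, design_candidates

            ranked = design_candidates(SynTCESpec(seed=0, n_candidates=64))
            best = next(c for c in ranked if c.passes)
            syntce_parts = [
                part_from_candidate(best, f"tce{i + 1}") for i in range(n_needed)
            ]
        else:
            syntce_parts = []
    syntce_parts = list(syntce_parts)
    if len(syntce_parts) != n_needed:
        raise LayoutError(
            f"{len(output_parts)} outputs need {n_needed} synTCE parts; "
            f"got {len(syntce_parts)}"
        )
    chain: List[Part] = switch_parts + [output_parts[0]]
    for syntce, orf in zip(syntce_parts, output_parts[1:]):
        chain.extend([syntce, orf])
    design = assemble_operon(chain)
    design.metadata["gate"] = gate
    design.metadata["inputs"] = inputs
    design.metadata["truth_table"] = _truth_table(gate, inputs)
    return design


def scan_internal_rbs(
    seq: NucSeq | str,
    anti_sd: str | None = None,
    model: EnergyModel | None = None,
    threshold: float | None = None,
    config: DesignConfig | None = None,
) -> List[Tuple[int, RBSScore]]:
    """Putative internal ribosome-entry sites in a sequence.

    Reports every AUG or GUG whose RBS-strength total falls below the
    configured threshold, ascending by position — the screen used to audit
    long linkers for internal initiation sites that erode coupling.
    """
    model = model or default_energy_model()
    config = config or default_config()
    asd = anti_sd if anti_sd is not None else config.anti_sd
    thr = threshold if threshold is not None else config.internal_rbs_threshold
    s = str(seq)
    hits: List[Tuple[int, RBSScore]] = []
    for p in range(len(s) - 2):
        if s[p:p + 3] in ("AUG", "GUG"):
            score = _rbs_at(s, p, asd, model, config)
            if score.total < thr:
                hits.append((p, score))
    return hits
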