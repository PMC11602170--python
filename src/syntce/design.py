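"""Generation, filtering, scoring and ranking of synTCE cassettes.

A synthetic translational coupling element (synTCE) is the cassette

    stem5 -- loop (containing the RBS) -- stem3 -- overlapping stop/start

placed between two ORFs of a polycistronic transcript.  The hairpin
(stem3 = revcomp(stem5)) sequesters the second RBS so that de novo
initiation is blocked; a ribosome terminating at the junction stop codon
unwinds it and reinitiates at the AUG that overlaps the stop codon by one
nucleotide (5'-URAUG-3', intergenic distance -1).

The generator randomizes the stem, rejects stems that create forbidden
nucleotide runs in the randomized domains, and applies three filters to
each assembled cassette: no premature in-frame stop codon, clean pattern
constraints, and a dominant designed hairpin of sufficient stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import DesignConfig, default_config
from .seqcore import (
    IUPACPattern,
    NucSeq,
    Region,
    SeqValidationError,
    STOP_CODONS,
    find_overlap_motif,
    revcomp,
    scan_stop_codons,
    to_rna,
)
from .thermo import (
    EnergyModel,
    RBSScore,
    StructureCheck,
    default_energy_model,
    hairpin_structure_check,
    local_structure_score,
    rbs_strength,
    stem_dG,
)

__all__ = [
    "SynTCESpec",
    "Candidate",
    "DesignError",
    "UnsatisfiableConstraintsError",
    "generate_stems",
    "assemble_syntce",
    "filter_candidate",
    "rank_candidates",
    "design_candidates",
]

DEFAULT_RBS = "AGAGGAGA"
#: Default loop: the purine-rich RBS with short mixed-sequence flanks.
#: Length 12 keeps stem5+loop+stem3 a multiple of 3 for the default 6-bp
#: stem, so the junction stop codon is read in the upstream ORF frame.
DEFAULT_LOOP = "ACAGAGGAGAUC"


class DesignError(ValueError):
    """Raised for invalid design specifications or layouts."""


class UnsatisfiableConstraintsError(DesignError):
    """Rejection sampling exhausted max_attempts with zero survivors."""


@dataclass(frozen=True)
class SynTCESpec:
    """A synTCE design request.

    The randomized degrees of freedom are the stem residues; the loop
    (which must contain the RBS), the overlap codon and the upstream
    context are fixed parts of the request.
    """

    stem_len: int = 6
    loop_seq: str = DEFAULT_LOOP
    rbs: str = DEFAULT_RBS
    overlap_codon: str = "UAA"
    upstream_context: Optional[str] = None
    pattern_constraints: Tuple[str, ...] = None  # None -> config defaults
    seed: int = 0
    n_candidates: int = 100
    max_attempts: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.stem_len <= 12:
            raise DesignError(
                f"stem_len must be within 0..12, got {self.stem_len}"
            )
        loop = str(to_rna(self.loop_seq))
        object.__setattr__(self, "loop_seq", loop)
        rbs = str(to_rna(self.rbs))
        object.__setattr__(self, "rbs", rbs)
        if rbs not in loop:
            raise DesignError("loop_seq must contain the RBS sequence")
        if not 8 <= len(loop) <= 20:
            raise DesignError(
                f"loop length must be within 8..20 nt, got {len(loop)}"
            )
        if self.overlap_codon not in ("UAA", "UGA"):
            raise DesignError(
                "overlap_codon must be UAA or UGA (URAUG requires R = A or G)"
            )
        if (2 * self.stem_len + len(loop)) % 3 != 0:
            raise DesignError(
                "frame error: stem5+loop+stem3 length must be a multiple of 3 "
                "so the junction stop codon is read in the upstream ORF frame"
            )
        if self.upstream_context is not None:
            object.__setattr__(
                self, "upstream_context", str(to_rna(self.upstream_context))
            )
        if self.pattern_constraints is None:
            object.__setattr__(
                self, "pattern_constraints", tuple(default_config().patterns)
            )
        else:
            object.__setattr__(
                self, "pattern_constraints", tuple(self.pattern_constraints)
            )
        for p in self.pattern_constraints:
            IUPACPattern(p)
        if self.n_candidates < 1:
            raise DesignError("n_candidates must be >= 1")

    @property
    def attempts_budget(self) -> int:
        if self.max_attempts is not None:
            return self.max_attempts
        return max(10_000, 100 * self.n_candidates)

    def spliced_upstream(self) -> str:
        """Upstream ORF tail with its own stop codon stripped.

        The synTCE junction stop replaces the ORF's terminator, so the
        upstream protein product is unchanged.
        """
        if self.upstream_context is None:
            return ""
        tail = self.upstream_context
        if len(tail) >= 3 and tail[-3:] in STOP_CODONS:
            tail = tail[:-3]
        if len(tail) % 3 != 0:
            raise DesignError(
                "frame error: upstream context length must be a multiple of 3 "
                "after removing its stop codon"
            )
        return tail


@dataclass(frozen=True)
class Candidate:
    """One assembled (and, after filtering, scored) synTCE cassette.

    ``regions`` are cassette-local coordinates; they tile the cassette with
    the single documented 1-nt stop/start overlap.  ``full_sequence`` is
    the spliced upstream context followed by the cassette — the mRNA
    context used for scoring.
    """

    cassette: NucSeq
    regions: Dict[str, Region]
    full_sequence: str
    junction_pos: int  # cassette-local position of the URAUG stop
    spec: SynTCESpec
    draw_index: int
    stem_dG: Optional[float] = None
    rbs_score: Optional[RBSScore] = None
    structure: Optional[StructureCheck] = None
    local_structure: Optional[float] = None
    flags: Dict[str, bool] = field(default_factory=dict)
    reasons: Dict[str, str] = field(default_factory=dict)

    @property
    def stem5(self) -> str:
        r = self.regions["stem5"]
        return self.cassette[r.start:r.end]

    @property
    def passes(self) -> bool:
        return bool(self.flags) and all(self.flags.values())

    @property
    def provenance(self) -> Tuple[int, int]:
        return (self.spec.seed, self.draw_index)

    @property
    def scored(self) -> bool:
        return self.structure is not None


def _variable_regions(spec: SynTCESpec) -> List[Region]:
    s, l = spec.stem_len, len(spec.loop_seq)
    if s == 0:
        return []
    return [Region(0, s, label="stem5"), Region(s + l, 2 * s + l, label="stem3")]


def _pattern_violations(
    cassette: str, spec: SynTCESpec
) -> List[Tuple[str, int]]:
    """(pattern, position) for every forbidden match that overlaps a
    randomized domain.  Matches entirely inside fixed domains (e.g. the
    8-purine RBS itself) are by design not violations."""
    variable = _variable_regions(spec)
    if not variable:
        return []
    hits = []
    for pat in spec.pattern_constraints:
        pattern = IUPACPattern(pat)
        for p in range(len(cassette) - len(pattern) + 1):
            if pattern.matches_at(cassette, p):
                window = Region(p, p + len(pattern))
                if any(window.overlaps(v) for v in variable):
                    hits.append((pat, p))
    return hits


def assemble_syntce(
    spec: SynTCESpec, stem5: str | NucSeq, draw_index: int = 0
) -> Candidate:
    """Assemble one cassette from a stem5 draw (unscored, unflagged).

    Layout: stem5 + loop + revcomp(stem5) + overlap_codon[0:2] + AUG, so
    the URAUG motif sits at the junction with the stop codon in the
    upstream reading frame.
    """
    stem5 = str(stem5)
    if len(stem5) != spec.stem_len:
        raise DesignError(
            f"stem5 length {len(stem5)} != spec.stem_len {spec.stem_len}"
        )
    if stem5:
        str(to_rna(stem5))
    s, l = spec.stem_len, len(spec.loop_seq)
    stem3 = str(revcomp(stem5)) if stem5 else ""
    cassette = stem5 + spec.loop_seq + stem3 + spec.overlap_codon[:2] + "AUG"
    junction = 2 * s + l
    rbs_off = spec.loop_seq.index(spec.rbs)
    regions = {
        "stem5": Region(0, s, label="stem5"),
        "loop": Region(s, s + l, label="loop"),
        "rbs": Region(s + rbs_off, s + rbs_off + len(spec.rbs), label="rbs"),
        "stem3": Region(s + l, junction, label="stem3"),
        "stop": Region(junction, junction + 3, frame=0, label="stop"),
        "start": Region(junction + 2, junction + 5,
                        frame=(junction + 2) % 3, label="start"),
    }
    upstream = spec.spliced_upstream()
    return Candidate(
        cassette=NucSeq(cassette),
        regions=regions,
        full_sequence=upstream + cassette,
        junction_pos=junction,
        spec=spec,
        draw_index=draw_index,
    )


def generate_stems(spec: SynTCESpec) -> List[str]:
    """Rejection-sample pattern-clean stem5 sequences (deterministic by seed).

    Draws uniform random stems of ``stem_len`` and keeps those whose
    insertion into the cassette creates no forbidden run overlapping a
    randomized domain.  Duplicates are dropped (first draw wins).  Stops at
    ``n_candidates`` distinct survivors or ``max_attempts`` draws; raises
    :class:`UnsatisfiableConstraintsError` if no stem ever survives.
    """
    if spec.stem_len == 0:
        return [""]
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGU"))
    survivors: List[str] = []
    seen = set()
    violation_counts: Dict[str, int] = {}
    for _ in range(spec.attempts_budget):
        stem = "".join(bases[rng.integers(0, 4, size=spec.stem_len)])
        if stem in seen:
            continue
        seen.add(stem)
        cassette = (
            stem + spec.loop_seq + str(revcomp(stem))
            + spec.overlap_codon[:2] + "AUG"
        )
        hits = _pattern_violations(cassette, spec)
        if hits:
            for pat, _ in hits:
                violation_counts[pat] = violation_counts.get(pat, 0) + 1
            continue
        survivors.append(stem)
        if len(survivors) >= spec.n_candidates:
            break
    if not survivors:
        binding = max(violation_counts, key=violation_counts.get) \
            if violation_counts else "(none recorded)"
        raise UnsatisfiableConstraintsError(
            f"no stem of length {spec.stem_len} satisfied the pattern "
            f"constraints within {spec.attempts_budget} attempts; most "
            f"frequently violated constraint: {binding}"
        )
    return survivors


def filter_candidate(
    candidate: Candidate,
    spec: SynTCESpec | None = None,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> Candidate:
    """Score a candidate and set its per-filter flags.

    Flags: ``no_premature_stop`` (no upstream-frame stop codon before the
    junction stop), ``patterns_clean`` (no forbidden run in randomized
    domains), ``structure`` (designed hairpin dominant and stable) and
    ``unique_junction`` (exactly one URAUG, at the annotated junction).
    Failures are flags with reasons, never exceptions.
    """
    spec = spec or candidate.spec
    model = model or default_energy_model()
    config = config or default_config()
    cassette = str(candidate.cassette)
    flags: Dict[str, bool] = {}
    reasons: Dict[str, str] = {}

    premature = [
        p for p in scan_stop_codons(cassette, 0) if p < candidate.junction_pos
    ]
    flags["no_premature_stop"] = not premature
    if premature:
        reasons["no_premature_stop"] = (
            f"in-frame stop codon(s) at cassette position(s) {premature}"
        )

    hits = _pattern_violations(cassette, spec)
    flags["patterns_clean"] = not hits
    if hits:
        reasons["patterns_clean"] = ", ".join(
            f"{pat}@{pos}" for pat, pos in hits[:5]
        )

    window = cassette[: 2 * spec.stem_len + len(spec.loop_seq)]
    structure = hairpin_structure_check(
        window, spec.stem_len, len(spec.loop_seq), model, config,
        rbs=candidate.regions["rbs"],
    )
    flags["structure"] = structure.passed
    if not structure.passed:
        reasons["structure"] = structure.reason

    motifs = find_overlap_motif(cassette)
    flags["unique_junction"] = motifs == [candidate.junction_pos]
    if not flags["unique_junction"]:
        reasons["unique_junction"] = f"URAUG motif(s) at {motifs}"

    start_abs = len(candidate.full_sequence) - 3
    score = rbs_strength(candidate.full_sequence, start_abs, None, model, config)
    local = local_structure_score(candidate.full_sequence, start_abs, model)
    return replace(
        candidate,
        stem_dG=stem_dG(candidate.stem5, model),
        rbs_score=score,
        structure=structure,
        local_structure=local,
        flags=flags,
        reasons=reasons,
    )


def rank_candidates(candidates: Sequence[Candidate]) -> List[Candidate]:
    """Deterministic ranking: passing candidates first, by ascending
    designed hairpin dG, then ascending RBS-strength total (stronger
    first), then lexicographic cassette as tie-break; failing candidates
    appended under the same key."""
    for c in candidates:
        if not c.scored:
            raise DesignError("rank_candidates requires scored candidates")

    def key(c: Candidate):
        return (
            0 if c.passes else 1,
            c.structure.designed_dG,
            c.rbs_score.total,
            str(c.cassette),
        )

    return sorted(candidates, key=key)


def design_candidates(
    spec: SynTCESpec,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> List[Candidate]:
    """Full pipeline: generate stems, assemble, filter/score, rank."""
    model = model or default_energy_model()
    config = config or default_config()
    stems = generate_stems(spec)
    scored = [
        filter_candidate(assemble_syntce(spec, stem, i), spec, model, config)
        for i, stem in enumerate(stems)
    ]
    return rank_candidates(scored)
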