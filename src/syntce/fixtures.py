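"""Seeded synthetic part generation.

Everything downstream of the design layer needs realistic ORFs, linkers
and (opaque) switch modules; this module produces them deterministically
from a seed so the whole pipeline is exercisable without any external
sequence data.  Generated ORFs satisfy the Part invariants (AUG start,
length divisible by 3, stop-free body, terminal stop); when
``exclude_sd_like`` is set, no window of the product can hybridize to the
default anti-Shine-Dalgarno tail with four or more contiguous pairs, so
fixture sequences carry no accidental internal ribosome-binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .assembly import Part
from .config import DesignConfig, default_config
from .seqcore import NucSeq, STOP_CODONS, SeqValidationError
from .thermo import is_pair

__all__ = [
    "FixtureSpec",
    "make_fixture_orf",
    "make_fixture_linker",
    "make_fixture_switch",
    "make_parts_registry",
    "max_asd_pair_run",
]

_BASES = np.array(list("ACGU"))
_CODONS = [
    a + b + c
    for a in "ACGU" for b in "ACGU" for c in "ACGU"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic part generator."""

    n_orfs: int = 3
    orf_length_range: Tuple[int, int] = (90, 300)  # nt, multiples of 3
    linker_length_range: Tuple[int, int] = (30, 90)
    gc_range: Tuple[float, float] = (0.30, 0.70)
    exclude_sd_like: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.orf_length_range, self.linker_length_range):
            if lo % 3 or hi % 3 or lo < 6 or hi < lo:
                raise SeqValidationError(
                    "length ranges must be multiples of 3 with 6 <= lo <= hi"
                )
        lo, hi = self.gc_range
        if not 0.0 < lo < hi < 1.0:
            raise SeqValidationError("gc_range bounds must lie strictly in (0, 1)")


def max_asd_pair_run(seq: str, anti_sd: Optional[str] = None) -> int:
    """Longest run of contiguous WC/GU pairs between *seq* and the anti-SD
    over every ungapped antiparallel alignment."""
    asd = (anti_sd if anti_sd is not None else default_config().anti_sd)[::-1]
    best = 0
    for offset in range(-(len(asd) - 1), len(seq)):
        run = 0
        for t in range(max(0, offset), min(len(seq), offset + len(asd))):
            if is_pair(seq[t], asd[t - offset]):
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _creates_internal_site(seq: str, new_from: int) -> bool:
    """True when a start codon beginning at or after *new_from* scores
    below the internal-RBS threshold.  Appending downstream never changes
    the (upstream-only) score of earlier positions, so checking the new
    triplets keeps the whole sequence clean incrementally."""
    from .config import default_config
    from .thermo import _rbs_at, default_energy_model

    config = default_config()
    model = default_energy_model()
    for p in range(max(0, new_from), len(seq) - 2):
        if seq[p:p + 3] in ("AUG", "GUG"):
            score = _rbs_at(seq, p, config.anti_sd, model, config)
            if score.total < config.internal_rbs_threshold:
                return True
    return False


def _grow_codons(
    rng: np.random.Generator,
    n_codons: int,
    prefix: str,
    exclude_sd_like: bool,
    anti_sd: str,
    max_codon_retries: int = 200,
) -> str:
    """Append stop-free codons to *prefix*, resampling any codon that
    creates an SD-like (>= 4 contiguous pair) window against the anti-SD
    or a start codon with a strong upstream anti-SD site."""
    seq = prefix
    for _ in range(n_codons):
        for attempt in range(max_codon_retries):
            codon = _CODONS[rng.integers(0, len(_CODONS))]
            if exclude_sd_like:
                tail = seq[-9:] + codon
                if max_asd_pair_run(tail, anti_sd) >= 4:
                    continue
                if _creates_internal_site(seq + codon, len(seq) - 2):
                    continue
            seq += codon
            break
        else:
            raise SeqValidationError(
                "fixture generation failed: could not extend sequence "
                f"without an SD-like window after {max_codon_retries} tries"
            )
    return seq


def make_fixture_orf(
    spec: FixtureSpec,
    name: str = "orf1",
    length: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 200,
) -> Part:
    """One synthetic ORF Part: AUG + stop-free body + UAA, GC within range."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    config = default_config()
    lo, hi = spec.orf_length_range
    for _ in range(max_attempts):
        n = length if length is not None else int(
            3 * rng.integers(lo // 3, hi // 3 + 1)
        )
        if n % 3 or n < 9:
            raise SeqValidationError(
                f"ORF length must be a multiple of 3 and >= 9, got {n}"
            )
        body = _grow_codons(rng, n // 3 - 2, "AUG",
                            spec.exclude_sd_like, config.anti_sd)
        seq = body + "UAA"
        if spec.exclude_sd_like and max_asd_pair_run(seq, config.anti_sd) >= 4:
            continue  # terminal stop created an SD-like window; redraw
        if spec.gc_range[0] <= _gc(seq) <= spec.gc_range[1]:
            return Part(name=name, role="orf", sequence=NucSeq(seq))
    raise SeqValidationError(
        f"could not generate an ORF meeting the GC range {spec.gc_range} "
        f"in {max_attempts} attempts"
    )


def make_fixture_linker(
    spec: FixtureSpec,
    name: str = "linker1",
    length: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Part:
    """A translated linker: stop-free codons, length a multiple of 3."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    config = default_config()
    lo, hi = spec.linker_length_range
    n = length if length is not None else int(3 * rng.integers(lo // 3, hi // 3 + 1))
    if n % 3:
        raise SeqValidationError(f"linker length must be a multiple of 3, got {n}")
    seq = _grow_codons(rng, n // 3, "", spec.exclude_sd_like, config.anti_sd)
    return Part(name=name, role="linker", sequence=NucSeq(seq))


def make_fixture_switch(
    name: str = "switch1",
    trigger: str = "trigA",
    length: int = 60,
    seed: int = 0,
) -> Part:
    """An opaque riboregulator switch placeholder (synthetic stand-in for a
    real toehold-switch part; only its length and trigger name matter to
    the assembler)."""
    if length % 3:
        raise SeqValidationError(
            f"switch length must be a multiple of 3 for frame continuity, "
            f"got {length}"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return Part(name=name, role="switch", sequence=NucSeq(seq),
                metadata={"trigger": trigger})


def make_parts_registry(spec: FixtureSpec) -> List[Part]:
    """A deterministic set of n_orfs ORFs plus one linker, one switch and
    one designed coupling cassette, enough to assemble a multi-output
    operon end to end."""
    from .design import SynTCESpec, design_candidates
    from .assembly import part_from_candidate

    rng = np.random.default_rng(spec.seed)
    parts = [
        make_fixture_orf(spec, name=f"orf{i + 1}", rng=rng)
        for i in range(spec.n_orfs)
    ]
    parts.append(make_fixture_linker(spec, name="linker1", rng=rng))
    parts.append(make_fixture_switch(seed=spec.seed))
    ranked = design_candidates(SynTCESpec(seed=spec.seed, n_candidates=16))
    best = next(c for c in ranked if c.passes)
    parts.append(part_from_candidate(best, "tce1"))
    return parts
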