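"""Package-wide tunable parameters and the YAML config file boundary.

One :class:`DesignConfig` instance carries every knob the scoring and
design layers expose: the anti-Shine-Dalgarno sequence, the spacing-penalty
shape, the hairpin stability threshold, the forbidden sequence patterns and
the search-window sizes.  All functions accept an explicit config and fall
back to :func:`default_config` so library use needs no file at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import List

import yaml

from .seqcore import IUPACPattern, NucSeq, to_rna

__all__ = ["DesignConfig", "default_config", "DEFAULT_PATTERNS", "DEFAULT_ANTI_SD"]

#: Forbidden runs of identical or chemically similar nucleotides used as
#: design pattern constraints (K = G/U, M = A/C, R = purine, S = strong,
#: W = weak, Y = pyrimidine).
DEFAULT_PATTERNS: List[str] = [
    "AAAA", "CCCC", "GGGG", "UUUU",
    "KKKKKK", "MMMMMM", "RRRRRR", "SSSSSS", "WWWWWW", "YYYYYY",
]

#: 3' tail of E. coli 16S rRNA (5'->3'); the mRNA Shine-Dalgarno sequence
#: hybridizes to this antiparallel.
DEFAULT_ANTI_SD = "ACCUCCUUA"


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters for scoring and design.

    Attributes
    ----------
    anti_sd:
        Anti-Shine-Dalgarno sequence (5'->3'), default the E. coli 16S
        rRNA 3' tail.
    optimal_spacing:
        Aligned spacing (nt) between the last SD-paired mRNA base and the
        start codon at which the spacing penalty is zero.
    spacing_stiffness_compressed / spacing_stiffness_stretched:
        Quadratic stiffness (kcal/mol/nt^2) on the compressed
        (spacing < optimum) and stretched sides.  Compression is penalised
        harder: the 30S footprint cannot be squeezed as easily as the
        spacer can be looped out.
    max_spacing:
        Spacing at which the stretched-side penalty is capped; also the
        penalty reported when no SD duplex is found at all.
    upstream_window:
        How far upstream of a start codon the anti-SD duplex search looks.
    structure_threshold:
        Maximum designed-hairpin free energy (kcal/mol) accepted by the
        structure check; default -6.0 — roughly a 6-bp mixed-composition
        stem, matching the minimum stem that suppressed de novo initiation.
    internal_rbs_threshold:
        RBS-strength total below which an internal AUG/GUG is reported as a
        putative internal ribosome entry site.
    patterns:
        Forbidden IUPAC runs applied to randomized design domains.
    """

    anti_sd: str = DEFAULT_ANTI_SD
    optimal_spacing: int = 5
    spacing_stiffness_compressed: float = 0.40
    spacing_stiffness_stretched: float = 0.10
    max_spacing: int = 15
    upstream_window: int = 20
    structure_threshold: float = -6.0
    internal_rbs_threshold: float = -4.5
    patterns: tuple = tuple(DEFAULT_PATTERNS)
    energy_table: str = ""  # empty -> packaged default table

    def __post_init__(self) -> None:
        to_rna(self.anti_sd)  # validates
        for p in self.patterns:
            IUPACPattern(p)  # validates
        if self.optimal_spacing < 0 or self.max_spacing <= self.optimal_spacing:
            raise ValueError("need 0 <= optimal_spacing < max_spacing")

    def pattern_objects(self) -> List[IUPACPattern]:
        return [IUPACPattern(p) for p in self.patterns]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "patterns" in data:
            data["patterns"] = tuple(data["patterns"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["patterns"] = list(data["patterns"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_(self, **kw) -> "DesignConfig":
        return replace(self, **kw)


_DEFAULT = DesignConfig()


def default_config() -> DesignConfig:
    """The package default configuration (a shared immutable instance)."""
    return _DEFAULT
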