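"""Nearest-neighbor free-energy layer.

Implements the thermodynamic quantities the design pipeline scores:

* ``stem_dG`` — free energy of a perfect hairpin-stem duplex, the sum of
  stacked-pair terms plus terminal A-U/G-U penalties.
* ``asd_duplex_dG`` — best hybridization energy of the 16S rRNA anti-SD
  tail against an mRNA window (ungapped alignment enumeration).
* ``spacing_penalty`` — piecewise-quadratic penalty for non-optimal
  distance between the SD duplex and the start codon.
* ``rbs_strength`` — the RBS-strength score: dG(rRNA:mRNA) + dG(spacing).
* ``hairpin_structure_check`` — confirms the designed hairpin is the most
  stable single-hairpin registration in its window and meets a stability
  threshold.

Energies are dG at 37 C in kcal/mol (1 M Na+, no Mg2+); parameters are a
Turner-2004-style table shipped as a versioned TSV.  An external folding
engine can be plugged in wherever a ``fold_engine`` callable mapping
sequence -> (structure, dG) is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Optional, Tuple

from .config import DesignConfig, default_config
from .seqcore import NucSeq, Region, SeqValidationError, to_rna

__all__ = [
    "EnergyModel",
    "RBSScore",
    "StructureCheck",
    "load_energy_model",
    "default_energy_model",
    "is_pair",
    "stem_dG",
    "asd_duplex_dG",
    "spacing_penalty",
    "rbs_strength",
    "hairpin_structure_check",
    "enumerate_hairpins",
    "local_structure_score",
]

_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
                    ("G", "U"), ("U", "G")})
_WEAK_CLOSING = frozenset({("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")})
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}

# Kuhn-length style logarithmic loop extrapolation beyond the tabulated
# sizes: dG(n) = dG(9) + 1.75 * R * T * ln(n / 9), RT at 310.15 K.
_RT37 = 0.0019872 * 310.15


def is_pair(a: str, b: str) -> bool:
    """Watson-Crick or G-U wobble pair."""
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor dG37 parameter set.

    ``stack_table`` maps the 36 ordered stacks ``"XY/WZ"`` (top strand
    5'-XY-3' over bottom strand 3'-WZ-5'; X pairs W, Y pairs Z, each pair
    one of AU, UA, CG, GC, GU, UG) to kcal/mol.  ``hairpin_table`` holds
    loop-initiation penalties for sizes 3..9; larger loops are extrapolated
    logarithmically.  ``terminal_AU_penalty`` is added once per helix end
    closed by an A-U or G-U pair.
    """

    stack_table: Dict[str, float]
    hairpin_table: Dict[int, float]
    terminal_AU_penalty: float
    temperature: str = "37C"

    def __post_init__(self) -> None:
        bases = {"A", "C", "G", "U"}
        expected = {
            f"{x}{y}/{w}{z}"
            for x in bases for y in bases for w in bases for z in bases
            if (x, w) in _PAIRS and (y, z) in _PAIRS
        }
        missing = expected - set(self.stack_table)
        if missing:
            raise ValueError(f"stack table incomplete: missing {sorted(missing)}")
        for size in range(3, 10):
            if size not in self.hairpin_table:
                raise ValueError(f"hairpin table missing loop size {size}")

    def stack(self, x: str, y: str, w: str, z: str) -> float:
        """dG of the stack 5'-XY-3' / 3'-WZ-5'."""
        try:
            return self.stack_table[f"{x}{y}/{w}{z}"]
        except KeyError:
            raise SeqValidationError(
                f"not an admissible stack: 5'{x}{y}3'/3'{w}{z}5'"
            ) from None

    def hairpin_loop(self, size: int) -> float:
        """Loop-initiation penalty for a hairpin loop of *size* nt (>= 3)."""
        if size < 3:
            raise SeqValidationError(f"hairpin loop must be >= 3 nt, got {size}")
        if size in self.hairpin_table:
            return self.hairpin_table[size]
        return self.hairpin_table[9] + 1.75 * _RT37 * math.log(size / 9.0)

    def terminal_penalty(self, a: str, b: str) -> float:
        return self.terminal_AU_penalty if (a, b) in _WEAK_CLOSING else 0.0


def load_energy_model(path: str | Path) -> EnergyModel:
    """Load a nearest-neighbor parameter TSV (stack / hairpin / terminal_au
    records); rotational symmetry XY/WZ == ZW/YX is filled in automatically."""
    stacks: Dict[str, float] = {}
    hairpins: Dict[int, float] = {}
    terminal = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                kind, key, value = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed record {line!r}")
            if kind == "stack":
                top, bottom = key.split("/")
                dg = float(value)
                stacks[key] = dg
                # 180-degree rotation of the duplex
                stacks[f"{bottom[::-1]}/{top[::-1]}"] = dg
            elif kind == "hairpin":
                hairpins[int(key)] = float(value)
            elif kind == "terminal_au":
                terminal = float(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {kind!r}")
    return EnergyModel(stacks, hairpins, terminal)


_default_model: Optional[EnergyModel] = None


def default_energy_model() -> EnergyModel:
    """The packaged Turner-2004-style parameter set (cached)."""
    global _default_model
    if _default_model is None:
        with resources.as_file(
            resources.files("syntce.data") / "rna_nn_dG37.tsv"
        ) as p:
            _default_model = load_energy_model(p)
    return _default_model


def stem_dG(stem5: NucSeq | str, model: EnergyModel | None = None) -> float:
    """Free energy of the perfect duplex stem5 : revcomp(stem5).

    Sum of the n-1 nearest-neighbor stacks plus a terminal penalty per
    A-U/G-U closing pair.  Empty or single-nucleotide stems have no stacks
    and return 0.
    """
    model = model or default_energy_model()
    s = str(stem5)
    if s:
        str(to_rna(s))  # validates residues
    n = len(s)
    if n < 2:
        return 0.0
    total = 0.0
    for k in range(n - 1):
        total += model.stack(s[k], s[k + 1], _COMP[s[k]], _COMP[s[k + 1]])
    total += model.terminal_penalty(s[0], _COMP[s[0]])
    total += model.terminal_penalty(s[-1], _COMP[s[-1]])
    return total


def _alignment_energy(
    win: str, bottom: str, offset: int, model: EnergyModel
) -> Tuple[float, List[int]]:
    """Energy and paired window-columns for one ungapped alignment.

    ``bottom`` is the anti-SD written 3'->5' (reversed), slid so that
    window column t faces bottom[t - offset].  Only contiguous runs of
    >= 2 pairs score, as nearest-neighbor stacks.
    """
    lo = max(0, offset)
    hi = min(len(win), offset + len(bottom))
    paired = [is_pair(win[t], bottom[t - offset]) for t in range(lo, hi)]
    energy = 0.0
    columns: List[int] = []
    run_start = None
    for i in range(len(paired) + 1):
        if i < len(paired) and paired[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= 2:
                for k in range(run_start, i - 1):
                    t = lo + k
                    energy += model.stack(
                        win[t], win[t + 1],
                        bottom[t - offset], bottom[t + 1 - offset],
                    )
                columns.extend(range(lo + run_start, lo + i))
            run_start = None
    return energy, columns


def _duplex_alignments(
    mrna: str, win_start: int, win_end: int, anti_sd: str, model: EnergyModel
) -> Iterator[Tuple[float, int, int, int]]:
    """Yield (energy, first_idx, last_idx, offset) for every alignment of
    the anti-SD against mrna[win_start:win_end] that scores at least one
    stack.  Indices are absolute mRNA coordinates."""
    win = mrna[win_start:win_end]
    bottom = anti_sd[::-1]
    for offset in range(-(len(bottom) - 1), len(win)):
        energy, columns = _alignment_energy(win, bottom, offset, model)
        if columns:
            yield energy, win_start + columns[0], win_start + columns[-1], offset


def asd_duplex_dG(
    mrna: NucSeq | str,
    window: Region,
    anti_sd: NucSeq | str,
    model: EnergyModel | None = None,
) -> Tuple[float, Region]:
    """Best (minimum) anti-SD : mRNA hybridization energy in a window.

    Enumerates every ungapped antiparallel alignment of the anti-SD against
    the window and scores contiguous runs of >= 2 Watson-Crick/G-U pairs
    with nearest-neighbor stacks.  Returns (0.0, empty Region) when no run
    of two pairs exists anywhere.
    """
    model = model or default_energy_model()
    s = str(mrna)
    asd = str(anti_sd)
    if len(asd) < 4:
        raise SeqValidationError("anti-SD must be at least 4 nt")
    if window.end > len(s):
        raise SeqValidationError(
            f"window [{window.start}, {window.end}) outside mRNA of length {len(s)}"
        )
    best = None
    for energy, first, last, offset in _duplex_alignments(
        s, window.start, window.end, asd, model
    ):
        key = (energy, offset)
        if best is None or key < best[0]:
            best = (key, energy, first, last)
    if best is None or best[1] >= 0.0:
        return 0.0, Region(window.start, window.start, label="no_duplex")
    _, energy, first, last = best
    return energy, Region(first, last + 1, label="asd_duplex")


@dataclass(frozen=True)
class RBSScore:
    """Decomposed RBS-strength score at one start codon.

    ``total = dG_rRNA_mRNA + dG_spacing`` exactly; more negative means a
    stronger predicted translation-initiation site.
    """

    dG_rRNA_mRNA: float
    dG_spacing: float
    total: float
    aligned_window: Region
    spacing: Optional[int]

    def __post_init__(self) -> None:
        if abs(self.total - (self.dG_rRNA_mRNA + self.dG_spacing)) > 1e-9:
            raise ValueError("RBSScore.total must equal the sum of its parts")
        if self.dG_spacing < 0:
            raise ValueError("spacing penalty cannot be negative")


def spacing_penalty(spacing: int, config: DesignConfig | None = None) -> float:
    """Penalty (kcal/mol) for non-optimal SD-to-start-codon spacing.

    Zero at the configured optimum (default 5 nt) and piecewise-quadratic
    away from it, with a stiffer compressed side.
    """
    config = config or default_config()
    if spacing < 0:
        raise SeqValidationError(f"spacing must be >= 0, got {spacing}")
    d = spacing - config.optimal_spacing
    if d < 0:
        return config.spacing_stiffness_compressed * d * d
    return config.spacing_stiffness_stretched * d * d


def _max_spacing_penalty(config: DesignConfig) -> float:
    return spacing_penalty(config.max_spacing, config)


def rbs_strength(
    mrna: NucSeq | str,
    start_pos: int,
    anti_sd: NucSeq | str | None = None,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
) -> RBSScore:
    """RBS-strength score dG(rRNA:mRNA) + dG(spacing) at an AUG.

    Searches a configurable upstream window (default 20 nt) for the
    minimum-energy anti-SD duplex; spacing is the gap between the last
    paired mRNA base and the start codon.  Ties in duplex energy resolve
    toward the spacing closest to the optimum.  With no duplex at all the
    score is the maximal configured spacing penalty.
    """
    config = config or default_config()
    model = model or default_energy_model()
    asd = str(anti_sd) if anti_sd is not None else config.anti_sd
    s = str(mrna)
    if s[start_pos:start_pos + 3] != "AUG":
        raise SeqValidationError(
            f"position {start_pos} is not an AUG start codon"
        )
    return _rbs_at(s, start_pos, asd, model, config)


def _rbs_at(
    s: str, start_pos: int, asd: str, model: EnergyModel, config: DesignConfig
) -> RBSScore:
    win_start = max(0, start_pos - config.upstream_window)
    best = None
    for energy, first, last, offset in _duplex_alignments(
        s, win_start, start_pos, asd, model
    ):
        if energy >= 0.0:
            continue
        spacing = start_pos - (last + 1)
        key = (energy, abs(spacing - config.optimal_spacing), -last)
        if best is None or key < best[0]:
            best = (key, energy, first, last, spacing)
    if best is None:
        penalty = _max_spacing_penalty(config)
        return RBSScore(0.0, penalty, penalty,
                        Region(start_pos, start_pos, label="no_duplex"), None)
    _, energy, first, last, spacing = best
    penalty = spacing_penalty(spacing, config)
    return RBSScore(energy, penalty, energy + penalty,
                    Region(first, last + 1, label="asd_duplex"), spacing)


def enumerate_hairpins(
    seq: NucSeq | str,
    model: EnergyModel | None = None,
    min_stem: int = 3,
    min_loop: int = 3,
) -> Iterator[Tuple[int, int, int, float]]:
    """All single-hairpin registrations in a window.

    Yields ``(i, j, L, dG)`` for every contiguous stem of length >= min_stem
    pairing positions (i+k, j-k), k = 0..L-1, enclosing a loop of
    >= min_loop nt.  dG = stack sum + terminal penalties + loop initiation.
    """
    model = model or default_energy_model()
    s = str(seq)
    n = len(s)
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            if not is_pair(s[i], s[j]):
                continue
            # grow the stem inward from the anchor pair (i, j)
            max_L = 1
            while True:
                k = max_L
                if (j - k) - (i + k) - 1 < min_loop:
                    break
                if not is_pair(s[i + k], s[j - k]):
                    break
                max_L += 1
            if max_L < min_stem:
                continue
            stack_sum = 0.0
            for L in range(2, max_L + 1):
                k = L - 2
                stack_sum += model.stack(
                    s[i + k], s[i + k + 1], s[j - k], s[j - k - 1]
                )
                if L < min_stem:
                    continue
                loop = (j - L + 1) - (i + L - 1) - 1
                dg = (
                    stack_sum
                    + model.terminal_penalty(s[i], s[j])
                    + model.terminal_penalty(s[i + L - 1], s[j - L + 1])
                    + model.hairpin_loop(loop)
                )
                yield i, j, L, dg


@dataclass(frozen=True)
class StructureCheck:
    """Outcome of the designed-hairpin structure check."""

    passed: bool
    designed_dG: float
    best_alt_dG: float
    reason: str = ""


def hairpin_structure_check(
    candidate_seq: NucSeq | str,
    stem_len: int,
    loop_len: int,
    model: EnergyModel | None = None,
    config: DesignConfig | None = None,
    rbs: Optional[Region] = None,
) -> StructureCheck:
    """Check that the designed hairpin dominates its sequence window.

    The window must be exactly stem5 + loop + stem3 (length
    2*stem_len + loop_len).  The designed structure passes iff (a) no
    *competing* single-hairpin registration in the window (exhaustive
    enumeration of contiguous stems >= 3 bp) is more stable than the
    designed energy ``stem_dG + loop_penalty``, and (b) it meets the
    configured stability threshold (default -6 kcal/mol).

    When ``rbs`` gives the RBS span in window-local coordinates, an
    alternative whose loop still encloses the whole RBS is not counted as
    competing: such registrations (e.g. the designed stem extended or
    shifted by one pair in quasi-palindromic stems) sequester the RBS at
    least as well as the designed fold and so achieve the design goal.
    Without ``rbs`` every non-designed registration competes.
    """
    model = model or default_energy_model()
    config = config or default_config()
    s = str(candidate_seq)
    if len(s) != 2 * stem_len + loop_len:
        raise SeqValidationError(
            f"window length {len(s)} != 2*{stem_len} + {loop_len}"
        )

    def competing(i: int, j: int, L: int) -> bool:
        if (i, j, L) == designed_key:
            return False
        if rbs is not None and i + L <= rbs.start and rbs.end <= j - L + 1:
            return False  # loop still encloses the RBS
        return True

    alternatives = list(enumerate_hairpins(s, model))
    designed_key = (0, len(s) - 1, stem_len)
    if stem_len == 0:
        designed_dG = model.hairpin_loop(loop_len)
    else:
        formable = all(
            is_pair(s[k], s[len(s) - 1 - k]) for k in range(stem_len)
        )
        if not formable:
            best_alt = min(
                (dg for i, j, L, dg in alternatives if competing(i, j, L)),
                default=math.inf,
            )
            return StructureCheck(False, math.inf, best_alt,
                                  "designed stem not formable")
        designed_dG = stem_dG(s[:stem_len], model) + model.hairpin_loop(loop_len)
    best_alt = min(
        (dg for i, j, L, dg in alternatives if competing(i, j, L)),
        default=math.inf,
    )
    if designed_dG > best_alt + 1e-9:
        return StructureCheck(False, designed_dG, best_alt,
                              "alternative hairpin more stable")
    if designed_dG > config.structure_threshold:
        return StructureCheck(False, designed_dG, best_alt,
                              f"designed dG {designed_dG:.2f} above threshold "
                              f"{config.structure_threshold:.2f}")
    return StructureCheck(True, designed_dG, best_alt)


FoldEngine = Callable[[str], Tuple[str, float]]


def local_structure_score(
    mrna: NucSeq | str,
    start_pos: int,
    model: EnergyModel | None = None,
    halfwindow: int = 15,
    fold_engine: Optional[FoldEngine] = None,
) -> float:
    """Windowed folding-energy score around a coupled start codon.

    Minimum single-hairpin free energy (capped above at 0 for an
    unstructured window) in the region +-halfwindow nt around the start
    codon.  More negative means more local structure obstructing
    post-termination ribosome scanning.  Any external folding engine
    (sequence -> (structure, dG)) can be substituted via ``fold_engine``.
    """
    s = str(mrna)
    lo = max(0, start_pos - halfwindow)
    hi = min(len(s), start_pos + 3 + halfwindow)
    window = s[lo:hi]
    if fold_engine is not None:
        _, dg = fold_engine(window)
        return min(0.0, dg)
    model = model or default_energy_model()
    best = min((dg for *_, dg in enumerate_hairpins(window, model)), default=0.0)
    return min(0.0, best)
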