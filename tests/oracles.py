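"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly against the parameter file and first
principles — no code is shared with the package's implementation paths.
"""

import math
from importlib import resources

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
_WEAK = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
_RT37 = 0.0019872 * 310.15


def load_table():
    """Hand-parse the packaged parameter TSV (own rotation fill)."""
    stacks, hairpins, terminal = {}, {}, 0.0
    path = resources.files("syntce.data") / "rna_nn_dG37.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            top, bot = key.split("/")
            stacks[(top, bot)] = float(value)
            stacks[(bot[::-1], top[::-1])] = float(value)
        elif kind == "hairpin":
            hairpins[int(key)] = float(value)
        elif kind == "terminal_au":
            terminal = float(value)
    return stacks, hairpins, terminal


STACKS, HAIRPINS, TERMINAL = load_table()


def loop_penalty(size):
    if size in HAIRPINS:
        return HAIRPINS[size]
    return HAIRPINS[9] + 1.75 * _RT37 * math.log(size / 9.0)


def stem_dg_by_hand(stem5):
    """Manual table summation for a perfect stem5:revcomp(stem5) duplex."""
    if len(stem5) < 2:
        return 0.0
    total = sum(
        STACKS[(stem5[k:k + 2], _COMP[stem5[k]] + _COMP[stem5[k + 1]])]
        for k in range(len(stem5) - 1)
    )
    for end in (stem5[0], stem5[-1]):
        if (end, _COMP[end]) in _WEAK:
            total += TERMINAL
    return total


def duplex_dg_by_enumeration(window, anti_sd):
    """Brute-force minimum duplex energy over every ungapped alignment.

    Scores every maximal run of >= 2 WC/GU pairs with stack terms; returns
    0.0 when nothing scores negatively.
    """
    bottom = anti_sd[::-1]
    best = 0.0
    for offset in range(-(len(bottom) - 1), len(window)):
        energy = 0.0
        run = []
        cols = list(range(max(0, offset), min(len(window), offset + len(bottom))))
        for t in cols + [None]:
            ok = t is not None and (window[t], bottom[t - offset]) in _PAIRS
            if ok:
                run.append(t)
            else:
                if len(run) >= 2:
                    for a in run[:-1]:
                        energy += STACKS[
                            (window[a:a + 2],
                             bottom[a - offset] + bottom[a + 1 - offset])
                        ]
                run = []
        best = min(best, energy)
    return best


def hairpins_by_enumeration(seq, min_stem=3, min_loop=3):
    """Every single-hairpin registration (i, j, L) -> dG, by direct triple
    loop over stem start, stem length and loop size."""
    n = len(seq)
    out = {}
    for i in range(n):
        for L in range(min_stem, n // 2 + 1):
            for loop in range(min_loop, n):
                j = i + 2 * L + loop - 1
                if j >= n:
                    break
                pairs = [(seq[i + k], seq[j - k]) for k in range(L)]
                if not all(p in _PAIRS for p in pairs):
                    continue
                dg = loop_penalty(loop)
                for k in range(L - 1):
                    dg += STACKS[
                        (seq[i + k:i + k + 2], seq[j - k] + seq[j - k - 1])
                    ]
                for p in (pairs[0], pairs[-1]):
                    if p in _WEAK:
                        dg += TERMINAL
                out[(i, j, L)] = dg
    return out


def spacing_penalty_closed_form(spacing, optimum, k_compressed, k_stretched):
    d = spacing - optimum
    return (k_compressed if d < 0 else k_stretched) * d * d
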