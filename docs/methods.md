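# Methods

## The design model

A synTCE cassette is `stem5 + loop + revcomp(stem5) + overlap[0:2] + AUG`,
where `overlap` is UAA or UGA, so the junction reads 5'-URAUG-3': the stop
codon of the upstream cistron shares one nucleotide with the start codon
of the next, giving intergenic distance −1 and shifting the downstream
reading frame by +2. Coordinates are 0-based half-open on the transcript;
the internal alphabet is RNA, with DNA transcribed at the I/O boundary.

**Frame constraint.** A ribosome entering the cassette from the upstream
ORF must read the junction stop codon in frame, so the cassette prefix
(stem5 + loop + stem3) must have length ≡ 0 mod 3. This is enforced at
spec construction. The default loop is therefore the 12-mer
`ACAGAGGAGAUC` (RBS `AGAGGAGA` with 2-nt flanks), inside the supported
8–20 nt range; supported stem lengths are 0–12 with default 6 — the
minimal length at which the hairpin reliably suppresses *de novo*
initiation. Translated linkers placed between an ORF and a cassette must
likewise be stop-free multiples of 3.

**Splice rule.** The upstream ORF's own stop codon is removed and replaced
by the junction stop. The ribosome consequently translates the linker and
the cassette prefix as extra C-terminal residues of the upstream protein;
the *downstream* protein begins exactly at the cassette's AUG, which is
the feature the architecture exists to guarantee.

**Pattern constraints** (`AAAA, CCCC, GGGG, UUUU, KKKKKK, MMMMMM, RRRRRR,
SSSSSS, WWWWWW, YYYYYY`) apply only to windows overlapping the randomized
stem domains. The fixed RBS is itself an 8-purine run; applying the
constraints globally would reject every design, so fixed domains are
exempt — constraints govern what the generator may *choose*, not what the
architecture prescribes. A consequence worth knowing: any all-{G,C} 6-mer
stem violates `SSSSSS`, so passing designs always have mixed-composition
stems.

**Generation** is rejection sampling (uniform stems, duplicates dropped,
deterministic in the seed via one named NumPy generator recorded in
candidate provenance), chosen over constraint propagation because the
domains are tiny and exactness is trivial to audit: at stem length 4 the
survivor set is checked against exhaustive enumeration of all 256 stems.
If no stem survives within the attempt budget the generator raises an
error naming the most frequently violated constraint.

**Ranking** is an explicit artifact decision (the design procedure selects
but states no objective): passing candidates by ascending designed hairpin
ΔG, then ascending RBS-strength total, then lexicographic cassette as a
deterministic tie-break; failing candidates follow with their reasons.

## Thermodynamics

Energies are nearest-neighbor ΔG°37 (kcal/mol) at 37 °C, 1 M Na+, no
Mg2+, from a packaged Turner-2004-style TSV: 21 unique stacks (rotations
filled by the loader, all 36 ordered stacks of the six admissible pairs
covered), hairpin-loop initiation penalties for sizes 3–9 with logarithmic
extrapolation `ΔG(n) = ΔG(9) + 1.75·RT·ln(n/9)` beyond, and a
0.45 kcal/mol penalty per helix end closed by A·U or G·U. The original
design work used a different published parameter set, so absolute values
are not comparable to that work's printed numbers; signs, rankings and
trends are the contract, and those are what the tests pin (e.g. replacing
any A·U stem pair with G·C never destabilizes — verified exhaustively over
random stems).

**Anti-SD duplex.** The anti-SD (default `ACCUCCUUA`, the E. coli 16S
rRNA 3' tail; configurable) is aligned ungapped and antiparallel at every
offset against the search window; contiguous runs of ≥ 2 Watson-Crick/G·U
pairs score as stacks; the minimum over alignments wins, ties resolving
toward spacing nearest the optimum. The implementation is checked against
an independently coded brute-force enumerator on random windows. With no
scoring run at all the RBS score falls back to zero duplex energy plus the
maximal spacing penalty.

**Spacing penalty.** Piecewise quadratic around the 5-nt optimum:
0.40·d² kcal/mol compressed, 0.10·d² stretched (compression is penalized
harder — the 30S footprint resists squeezing more than a spacer resists
looping out). The two stiffnesses and the optimum are configuration
values; only the two summed terms (duplex + spacing) are modeled — standby
and long-range unfolding terms of full initiation calculators are
deliberately out of scope.

**Structure check.** Every single-hairpin registration (contiguous stems
≥ 3 bp, loops ≥ 3 nt) in the cassette window is enumerated exhaustively —
windows are < 60 nt, so this is cheap and exact within the single-hairpin
model (no multi-helix folds, pseudoknots or co-transcriptional effects).
A design passes when its hairpin energy (stem ΔG + loop penalty) meets the
−6 kcal/mol threshold **and** no *competing* registration is more stable.
A registration whose loop still encloses the whole RBS is not competing:
for quasi-palindromic stems the window minimum is the designed hairpin
shifted or extended by one pair, which sequesters the RBS at least as well
— treating it as a rival would reject designs that achieve the design
goal. Callers that know the RBS span pass it; without it the strict
designed-is-minimum rule applies. An external folding engine can be
substituted anywhere via a `fold_engine` callable mapping sequence →
(structure, ΔG); the packaged ViennaRNA bindings are used this way in a
trend cross-check test, never as the implementation.

**Local-structure score.** The statistic correlating local mRNA structure
with reinitiation efficiency is not fully specified in its source; the
package ships a clearly labeled stand-in — the minimum single-hairpin
energy (capped at 0) in a ±15-nt window around the coupled start codon —
and makes no parity claim for it.

## Assembly and validation

The operon grammar is `switch* orf (linker? syntce orf)*`. Assembly is
junction-local, which makes chaining associative (extending an assembled
two-output design equals assembling the three-output list directly —
tested residue-for-residue). Every assembled transcript is re-parsed
before it is returned: each cistron must start at AUG, read stop-free in
its annotated frame to its terminating stop, and each junction must carry
URAUG at the annotated position.

Junction reports classify intergenic distance as "optimal" (−1..5, the
experimentally effective range), "degrading" (6..14) or "poor" (≥ 15); the
6/15 split is an artifact convention for graded warnings over a reported
gradual decay. Upstream cistron runs longer than 1000 nt add a
dynamic-range-decay warning, and beyond 3000 nt a convergence warning
(thresholds from the reported >1 kb decay and 3 kb ON/OFF convergence).
Gate layouts treat switches as opaque parts — only length (≡ 0 mod 3, for
frame continuity across concatenated modules) and order are enforced — and
record a qualitative truth-table stub per input combination; no kinetics
are simulated. OR/NAND gates accept 2–6 switch modules (six being the
demonstrated maximum), AND/NIMPLY one switch with two named trigger
domains.

The internal-RBS scan reports every AUG/GUG whose RBS-strength total falls
below −4.5 kcal/mol (configurable) — the audit used on long linkers, whose
putative internal sites erode coupling.

## Analysis conventions

Fluorescence distributions are treated as log-normal: averages are
geometric means, and "relative error" is the sample standard deviation of
the raw replicates divided by the geometric mean (the normalizer is a
documented convention; it is configurable by computing from the raw
values). Fold change = geomean(ON)/geomean(OFF) with relative errors added
in quadrature. Regression is ordinary least squares on raw response by
default with a log10 option — which scale underlay the original
correlations is not stated, so both are exposed. CFU/ml = colonies ×
dilution / 0.005 ml (5 µl spotted).

## Synthetic fixtures

The fixture generator emulates the *structural* properties of real parts:
ORFs start with AUG, end with UAA, are stop-free in frame, and sit inside
a GC window (default 0.30–0.70); linkers are stop-free codon runs;
switches are random in-frame placeholders labeled synthetic. With
`exclude_sd_like` set, codons are resampled whenever they would create a
≥ 4-pair contiguous anti-SD hybrid or a start codon scoring below the
internal-RBS threshold — since RBS windows look only upstream, this
incremental screen is exact, and generated parts carry no accidental
initiation sites *by construction*. Fixtures deliberately do not emulate
codon-usage bias, real gene composition, mRNA-level effects or ribosome
kinetics; passing tests therefore demonstrate correctness of the design
arithmetic and scoring on realistic-shaped inputs, not predictions about
any particular biological sequence.

## Problem sizes and numerical choices

The constraint-satisfaction suite draws 1000 stem-6 candidates;
enumeration equivalence runs at stem length 4 (256 stems, where the
passing set is empty under the default threshold — a 4-bp stem cannot
reach −6 kcal/mol, which is exactly why the minimal effective architecture
uses 6 bp — while the pattern-survivor sets are compared non-trivially);
thermodynamic oracles use 100 random ≤ 30-nt windows and 20 stems. Float
comparisons in the structure check use a 1e-9 tolerance for tie-breaking
(ties count as "designed is dominant"). All randomness flows through
seeded NumPy generators; outputs carry a fixed GenBank date stamp so runs
are byte-reproducible.

## Known limitations

Single-hairpin enumeration ignores multi-helix and long-range structure;
the energy table omits salt corrections, dangling ends and special-loop
bonuses; the RBS model omits standby-site and unfolding terms; switch
internals and gate kinetics are not modeled; and the local-structure score
is a stand-in statistic. Measured fold changes and correlations from
wet-lab experiments are outside what this package can reproduce — its
guarantees are the constraint, trend, integrity and determinism properties
its test suite computes.
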