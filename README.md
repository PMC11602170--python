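# syntce

Design toolkit for **synthetic translational coupling elements** (synTCEs):
hairpin cassettes placed between the open reading frames of a polycistronic
mRNA so that translation of each downstream gene requires ribosomes
completing the upstream one.

## The problem

Synthetic riboregulators such as toehold switches control one downstream
ORF, leak sequence onto the output protein's N-terminus, and cannot drive
further genes on the same transcript. A synTCE solves all three problems
with a compact cassette:

```
5'- [stem5] [loop containing the RBS] [stem3 = revcomp(stem5)] U(A/G)A UG -3'
                                                               └ stop ┘└ start
```

The stem sequesters the second ribosome-binding site (RBS, default
`AGAGGAGA`) so *de novo* initiation is blocked; a ribosome terminating at
the junction stop codon — which overlaps the downstream start codon by one
nucleotide (the 5'-URAUG-3' motif, intergenic distance −1) — has already
unwound the hairpin and reinitiates at the exposed RBS. Chaining cassettes
yields multi-output operons with defined stoichiometry and exact N-termini.

The package generates randomized-stem cassettes, filters them the way the
design procedure requires (no in-frame stop codon before the junction; no
forbidden nucleotide runs `AAAA, CCCC, GGGG, UUUU, K6, M6, R6, S6, W6, Y6`
in randomized domains; a dominant, sufficiently stable designed hairpin),
scores them thermodynamically, and compiles parts into annotated operon
transcripts and ribocomputing gate layouts (OR/AND/NAND/NIMPLY).

## The scores

All energies are nearest-neighbor ΔG°37 in kcal/mol (Turner-2004-style
stack and loop parameters shipped as a packaged TSV):

* **stem ΔG** — sum of stacked-pair terms of the perfect stem duplex plus
  terminal A·U/G·U penalties; the designed hairpin energy adds the
  loop-initiation penalty.
* **RBS strength** = ΔG<sub>rRNA:mRNA</sub> + ΔG<sub>spacing</sub> — the
  minimum hybridization energy of the 16S rRNA anti-SD tail
  (`ACCUCCUUA`) over all ungapped alignments in a 20-nt window upstream of
  the start codon, plus a piecewise-quadratic penalty for non-optimal
  spacing (optimum 5 nt). More negative = stronger initiation.
* **structure check** — exhaustive enumeration of every single-hairpin
  registration in the cassette window; the design passes when its hairpin
  reaches −6 kcal/mol and no competing fold (one that fails to enclose the
  RBS in its loop) is more stable.
* **analysis utilities** — fold change as the ratio of geometric-mean ON to
  OFF fluorescence with relative errors combined in quadrature; ordinary
  least-squares feature-vs-output regression; CFU/ml = colonies ×
  dilution / 0.005 ml.

## Worked example

```python
from syntce import SynTCESpec, design_candidates

ranked = design_candidates(SynTCESpec(stem_len=6, seed=42, n_candidates=50))
passing = [c for c in ranked if c.passes]
print(len(passing), str(passing[0].cassette))
```

prints `8 GGCUGCACAGAGGAGAUCGCAGCCUAAUG`: 8 of 50 seeded candidates pass
all filters, and the top-ranked cassette reads stem5 `GGCUGC`, the
RBS-bearing loop `ACAGAGGAGAUC`, stem3 `GCAGCC` and the overlapping
stop–start `UAAUG`. Its scores (see `examples/design_cassettes.py`) are
stem ΔG −14.29 kcal/mol, designed hairpin ΔG −7.58 kcal/mol (stable and
dominant) and RBS strength −7.17 kcal/mol at the coupled AUG.

The `examples/` directory holds one short script per capability: cassette
design, thermodynamic scoring, three-output operon assembly with GenBank
export, logic-gate layout with truth tables, and measurement regression.

A thin CLI mirrors the library: `syntce design | assemble | validate |
score | fit | fixtures`, each seeded and byte-reproducible.

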