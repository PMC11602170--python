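"""Design and rank synTCE cassette candidates.

Generates 50 seeded 6-bp-stem cassettes, applies the three design filters
(no premature in-frame stop, clean pattern constraints, dominant stable
hairpin) and prints the top-ranked survivors.
"""

from syntce import SynTCESpec, design_candidates

spec = SynTCESpec(stem_len=6, seed=42, n_candidates=50)
ranked = design_candidates(spec)
passing = [c for c in ranked if c.passes]

print(f"{len(passing)}/{len(ranked)} candidates pass all filters\n")
print(f"{'cassette':<31} {'stem dG':>8} {'hairpin dG':>11} {'RBS total':>10}")
for cand in passing[:5]:
    print(f"{str(cand.cassette):<31} {cand.stem_dG:>8.2f} "
          f"{cand.structure.designed_dG:>11.2f} {cand.rbs_score.total:>10.2f}")

best = passing[0]
print(f"\nTop candidate stem5 = {best.stem5}; regions:")
for name, region in best.regions.items():
    print(f"  {name:<6} [{region.start:>2}, {region.end:>2})  "
          f"{str(best.cassette)[region.start:region.end]}")

# stem dG is the hairpin duplex free energy (more negative = more stable);
# hairpin dG adds the loop-initiation penalty; RBS total is
# dG(rRNA:mRNA) + dG(spacing) at the coupled start codon (more negative =
# stronger reinitiation site).  Ranking: stable hairpin first, then strong
# RBS, then lexicographic tie-break.
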