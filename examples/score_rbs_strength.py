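"""Score RBS strength and hairpin stability for hand-built sequences.

Shows the two terms of the RBS-strength score on a synthetic mRNA and the
stem free-energy trend from weak (A-U) to strong (G-C) pairs.
"""

from syntce import (
    NucSeq,
    hairpin_structure_check,
    rbs_strength,
    revcomp,
    stem_dG,
)
from syntce.seqcore import Region

# SD site, a 4-nt spacer, then the start codon
mrna = NucSeq("CUCUCUCUCU" + "AGAGGAGA" + "CCCC" + "AUGGCU")
score = rbs_strength(mrna, 22)
print("RBS strength at the AUG:")
print(f"  dG rRNA:mRNA = {score.dG_rRNA_mRNA:6.2f} kcal/mol "
      f"(anti-SD duplex over mRNA {score.aligned_window.start}.."
      f"{score.aligned_window.end})")
print(f"  dG spacing   = {score.dG_spacing:6.2f} kcal/mol "
      f"(spacing {score.spacing} nt)")
print(f"  total        = {score.total:6.2f} kcal/mol\n")

print("Stem stability by base composition (6-bp stems):")
for stem5 in ("AUAUAU", "AUGCAU", "GCAUGC", "GCCAGC", "GCGCGC"):
    print(f"  {stem5}: stem dG = {stem_dG(stem5):7.2f} kcal/mol")

loop = "ACAGAGGAGAUC"
window = "GCCAGC" + loop + str(revcomp("GCCAGC"))
check = hairpin_structure_check(window, 6, 12, rbs=Region(8, 16))
print(f"\nStructure check for GCCAGC hairpin: pass={check.passed}, "
      f"designed dG {check.designed_dG:.2f}, best competing alternative "
      f"{check.best_alt_dG:.2f} kcal/mol")
# A design passes when its hairpin meets the -6 kcal/mol stability
# threshold and no competing fold (one that fails to sequester the RBS)
# is more stable.
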