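"""Detect homologous repeat regions (hrs) and display their consensus.

hrs are clusters of imperfect palindromes (49-83 bp here) whose arms begin
with the inverted terminal-repeat consensus TGATGACGAA.  The detector
enumerates palindromic windows within a 15% per-arm mismatch tolerance,
clusters them within 1 kb, and aligns the member repeats: uppercase
consensus letters mark fully conserved columns, lowercase marks majority
columns.
"""

from gvkit.hrs import find_hrs, hr_consensus
from gvkit.simulate import PRESETS, generate_genome

genome, truth = generate_genome(PRESETS["easy"], seed=7)
regions = find_hrs(genome)

print(f"planted hrs: {len(truth.hrs)}, detected: {len(regions)}")
for r in regions:
    tr = sum(1 for _ in r.terminal_repeat_hits)
    print(f"  {r.name}  {r.span.start}-{r.span.end}  "
          f"{len(r.palindromes)} palindrome(s), {tr} terminal-repeat hits")

repeats = [genome.fetch(p.span.start, p.span.end) for r in regions for p in r.palindromes]
labels = [f"{p.span.start}-{p.span.end}" for r in regions for p in r.palindromes]
display = hr_consensus(repeats, labels)
print("\nrepeat alignment and case-coded consensus:")
print(display.render())
# Each detected region should match one planted hr; the consensus line
# starts and ends with the (fully conserved) terminal repeat in uppercase.
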