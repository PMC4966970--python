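"""Gene parity (synteny) comparison between two related annotations.

Orthologues are assigned by reciprocal best hit between the proteomes.
Each ORF becomes one parity point (x = number in A, y = number in B);
ORFs private to one genome sit on that genome's axis.  The breakpoint
statistic counts adjacent orthologue pairs in A whose partners are not
adjacent in B: 0 means perfectly conserved gene order, an inverted or
relocated block adds 2.
"""

import random

from gvkit.parity import gene_parity_table, reciprocal_best_hits, synteny_breakpoints
from gvkit.simulate import PRESETS, generate_genome, generate_proteome

genome, truth = generate_genome(PRESETS["easy"], seed=7)
proteome_a = [(f"A{o.index}", o.aa) for o in truth.orfs]

# genome B: same gene set diverged by 25%, with a relocated 3-gene block
diverged = dict(generate_proteome(truth, 0.25, seed=8, n_decoys=0))
order = [o.index for o in truth.orfs if o.has_homolog]
block, rest = order[4:7], order[:4] + order[7:]
order_b = rest + block
proteome_b = [(f"B{i}", diverged["granulin_ref" if i == 1 else f"ref_{i:03d}"]) for i in order_b]

om = reciprocal_best_hits(proteome_a, proteome_b, seed=1)
table = gene_parity_table(om, [o.index for o in truth.orfs], list(range(1, len(proteome_b) + 1)))
bp = synteny_breakpoints(table)

print(f"orthologue pairs: {len(om.pairs)} of {len(proteome_a)} ORFs")
print(f"synteny breakpoints: {bp}")
off_diag = [(x, y) for x, y, c in table.points if c == "pair" and x != y]
print(f"off-diagonal parity points: {len(off_diag)} "
      "(the relocated block, plus everything renumbered downstream of it)")
# With one relocated block the plot is diagonal except around the move,
# and the breakpoint count is small but non-zero (2 for a clean block move).
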