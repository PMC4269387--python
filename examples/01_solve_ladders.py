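"""Solve Doublets word-ladder puzzles on small printed word sets.

Builds the ladder graph over a handful of words and finds shortest ladders;
the step count (number of intermediate words) is the puzzle's difficulty.
"""

import doubletsnet as dn
from doubletsnet import synth

for key, fixture in synth.printed_ladders().items():
    lad = dn.build_ladder_graph(fixture.words)
    sol = dn.solve_doublet(lad, fixture.source, fixture.target)
    print(f"{fixture.source} -> {fixture.target}:  {' '.join(sol.words)}")
    print(f"  steps (intermediate words): {sol.steps}")

# Steps = edges - 1: the LOVE->HATE ladder uses 3 one-letter changes but
# passes through 2 intermediate words, so its difficulty is 2.
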