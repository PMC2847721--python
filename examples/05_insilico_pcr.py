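"""Predict amplicon sizes for a primer panel by in-silico PCR.

The published BDNF assay primers are planted on a synthetic transcript
with the published 101-bp spacing; the matcher locates both sites and
reports 1-based inclusive product coordinates.
"""

import numpy as np

from earnorm import PrimerPair, find_amplicons
from earnorm.insilico_pcr import reverse_complement

bdnf = PrimerPair("BDNF", "TAACGGCGGCAGACAAAAAGA",
                  "GAAGTATTGCTTCAGTTGGCCT", expected_product_bp=101)

rng = np.random.default_rng(11)
spacer_len = bdnf.expected_product_bp - len(bdnf.forward) - len(bdnf.reverse)
spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
pad = "".join(rng.choice(list("ACGT"), size=40))
template = pad + bdnf.forward + spacer + reverse_complement(bdnf.reverse) + pad

for hit in find_amplicons(bdnf, template, sequence_id="synthetic_BDNF_tpl"):
    print(f"{hit.sequence_id}: product {hit.start}..{hit.end} "
          f"({hit.length_bp} bp), mismatches fwd={hit.fwd_mismatches} "
          f"rev={hit.rev_mismatches}")
print()
print("One clean hit of the expected 101 bp; multiple or missing hits")
print("would flag a primer design or template problem.")
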