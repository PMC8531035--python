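"""Tissue specificity of candidate target genes: tau and per-tissue z-scores.

tau = 1 flags single-tissue genes (clean pharmacology), tau = 0 flags
housekeeping genes (higher adverse-event potential); tissues with z > 1
are where the gene's expression is elevated relative to the rest.
"""

import numpy as np

from targetmr.tissue import ExpressionProfile, score_gene

tissues = ["liver", "kidney", "brain", "heart", "intestine", "muscle"]
profiles = [
    ExpressionProfile("liver-specific", np.array([80, 0, 0, 0, 0, 0.0]), tissues),
    ExpressionProfile("housekeeping", np.full(6, 12.0), tissues),
    ExpressionProfile("liver-enriched", np.array([60, 8, 2, 5, 20, 3.0]), tissues),
]

for p in profiles:
    s = score_gene(p)
    top = ", ".join(f"{t} (z={z:.2f})" for t, z in s.top_tissues) or "none"
    print(f"{p.gene_id:16s} tau = {s.tau:.2f}   top tissues: {top}")

# The liver-specific gene scores tau = 1.00 with liver as its only elevated
# tissue; the housekeeping gene scores tau = 0 with no elevated tissue.
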