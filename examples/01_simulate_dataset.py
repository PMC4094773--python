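"""Generate the synthetic study dataset and summarize what was planted.

The generator emulates a strand-specific RNA-seq study of a developing
tissue: a toy genome, annotated genes, assembled transcript contigs, an
expression time course over 14 individuals aged 2 days to 98 years, CAGE
tags, chromatin/conservation tracks, and a TRANSFAC-format motif library.
Truth tables record every planted element for recovery scoring.
"""

import pandas as pd

from _shared import dataset

sim = dataset()
promoters = pd.read_csv(sim / "truth/promoters.tsv", sep="\t")
elements = pd.read_csv(sim / "truth/elements.tsv", sep="\t")

print("\nplanted promoter classes:")
print(promoters["klass"].value_counts().to_string())
print("\nplanted novel elements of annotated genes:")
print(elements["kind"].value_counts().to_string())
print("\nEach NBiP row pairs an annotated gene with a novel antisense")
print("transcript whose TSS lies within 2 kb head-to-head; these are the")
print("promoters the downstream examples try to recover.")
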