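"""Scan promoter windows with TRANSFAC matrices and test NBiP enrichment.

MATCH-style scoring (matrix and core similarity) finds binding-site hits in
NBiP and KBiP windows; Fisher's exact test per matrix with BH correction and
an odds-ratio > 1.3 filter flags enriched motifs, and a dinucleotide-shuffle
null band localizes the planted motif's positional peak.
"""

import pyfaidx

from _shared import dataset
from nbipscan import (
    annotate_status,
    call_promoters,
    density_profile,
    enrich,
    merge_contigs,
    read_transfac,
    scan,
)
from nbipscan import io as nio

sim = dataset()
genes = nio.read_annotation(sim / "annotation.gtf")
clusters = annotate_status(merge_contigs(nio.read_bed12(sim / "contigs.bed12")), genes)
calls = call_promoters(genes, clusters)
genome = pyfaidx.Fasta(str(sim / "genome.fa"))
pwms = read_transfac(sim / "matrices.dat")

windows = {"NBiP": [], "KBiP": []}
nbip_hits, kbip_hits = [], []
for c in calls:
    group = ("NBiP" if c.klass == "NBiP"
             else "KBiP" if c.klass in ("pcKBiP", "lncKBiP") else None)
    if group is None:
        continue
    seq = genome[c.chrom][c.window.start:c.window.end].seq.upper()
    windows[group].append(seq)
    for pwm in pwms:
        hits = scan(seq, pwm, promoter_id=c.anchor_gene_id)
        (nbip_hits if group == "NBiP" else kbip_hits).extend(hits)

table, enriched, _ = enrich(nbip_hits, kbip_hits,
                            len(windows["NBiP"]), len(windows["KBiP"]))
print(f"scanned {len(pwms)} matrices over {len(windows['NBiP'])} NBiP and "
      f"{len(windows['KBiP'])} KBiP windows")
for r in table:
    flag = "  <-- enriched" if r in enriched else ""
    print(f"  {r.label:16s} NBiP {r.a:3d}/{r.a + r.b:3d}  "
          f"KBiP {r.c:3d}/{r.c + r.d:3d}  OR={r.odds_ratio:6.2f}  "
          f"q={r.q:.3g}{flag}")

prof = density_profile(windows["NBiP"], pwms[0], n_shuffles=100, seed=0)
print(f"\npositional profile of {pwms[0].matrix_id}: central peak above the "
      f"shuffle band: {prof['central_peak']}")
print("The planted matrix should be the only one passing q < 0.05 with")
print("OR > 1.3, with its hits concentrated at the promoter center.")
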