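"""Promoter boxes upstream of the inverted trnD gene.

trnD is transcribed antisense to its neighbours trnY/trnE, so it cannot
share their operon promoter; a sigma70-style -35/-10 pair on its own
strand, upstream of the gene, supports independent transcription.  This
example scans the upstream window of trnD in a simulated record carrying
a planted box pair.
"""

from fernbz.promoters import scan_promoters
from fernbz.simulate import simulate_region, vandenboschia_like_config

aseq, truth = simulate_region(vandenboschia_like_config(seed=5))
trnd = aseq.feature_by_locus("trnD-GUC")
print(f"trnD-GUC at {trnd.start}..{trnd.end} on strand {trnd.strand}")

# for a minus-strand gene, "upstream" lies to the right in forward coords
window = (trnd.end + 1, trnd.end + 200)
hits = [h for h in scan_promoters(aseq.residues, window) if h.strand == "-"]
print(f"scan window {window[0]}..{window[1]}, hits on the gene strand: {len(hits)}")
for h in hits:
    print(f"  -35 {h.minus35_seq} at {h.minus35[0]}..{h.minus35[1]}, "
          f"spacer {h.spacer} nt, -10 {h.minus10_seq} at "
          f"{h.minus10[0]}..{h.minus10[1]}  ({h.total_mismatches} mismatches)")
print(
    "\nA box pair on the trnD strand within the upstream window is consistent"
    "\nwith trnD transcription independent of the trnE operon."
)
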