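# Approximate 1-based coordinates, within a plastid trnY-GUA gene, of the
# 25-nt window spanning the D-arm stem plus the entire anticodon arm
# (anticodon stem-loop). Configurable: pass an explicit region to
# tandem.anticodon_similarity to override.
locus	start	end
trnY-GUA	19	43
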