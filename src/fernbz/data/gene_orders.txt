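# Catalog of named BZ (rpoB..psbZ) gene orders in ferns, one per line:
# name <TAB> comma-separated signed single-letter symbols, read in the
# rpoB -> psbZ direction with rpoB (B) forced to + sign.
#
# Transcription of the published gene-organization diagrams. Established
# constraints: trnD (D) is antisense to trnY/trnE (Y, E) in every
# type; the "CE inversion" (segment trnC..trnE) converts the Angiopteris
# type into the Plagiogyria type; the "DE inversion" (the DYE block)
# converts the Plagiogyria type into the Adiantum type. The orientations
# of N and M follow from those constraints; G and Z orientations are
# diagram-only and recorded here as +.
Angiopteris	B,C,-N,-M,-D,Y,E,G,Z
Plagiogyria	B,-E,-Y,D,M,N,-C,G,Z
Adiantum	B,-D,Y,E,M,N,-C,G,Z
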