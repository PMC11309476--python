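# Default registry of 14 candidate causal models over the five variables
#   GS   genome size (log10)
#   CV   minimum cell volume (log10)
#   DT   doubling time (log10)
#   TEMP growth temperature (deg C)
#   GC   genomic GC content (%)
#
# Three families: null models (genome size has no effect, direct or
# indirect, on doubling time), direct models (a GS -> DT edge), and
# indirect models (GS reaches DT only through cell volume).
#
# The registry is a reconstruction: it honors the documented structural
# constraints of the published 14-model set (direct4 = GS->CV, GS->DT,
# TEMP->GS, TEMP->DT with GC->GS retained; direct2 swaps GS->CV for
# CV->GS and, like direct1, omits GC->GS; indirect models route genome
# size to doubling time only via cell volume), with the remaining edge
# lists filled in by the same logic. Users can supply their own file in
# this format to replace it.

[null1]
CV -> DT
TEMP -> DT

[null2]
CV -> DT
TEMP -> DT
TEMP -> GS

[null3]
CV -> DT
TEMP -> DT
TEMP -> GS
GC -> GS

[null4]
CV -> DT
TEMP -> DT
CV -> GS
TEMP -> GS

[direct1]
GS -> CV
GS -> DT
TEMP -> GS
TEMP -> DT

[direct2]
CV -> GS
GS -> DT
TEMP -> GS
TEMP -> DT

[direct3]
CV -> GS
GS -> DT
TEMP -> GS
TEMP -> DT
GC -> GS

[direct4]
GS -> CV
GS -> DT
TEMP -> GS
TEMP -> DT
GC -> GS

[direct5]
GS -> DT
CV -> DT
TEMP -> GS
TEMP -> DT
GC -> GS

[indirect1]
GS -> CV
CV -> DT
TEMP -> GS
TEMP -> DT

[indirect2]
GS -> CV
CV -> DT
TEMP -> GS
TEMP -> DT
GC -> GS

[indirect3]
GS -> CV
CV -> DT
TEMP -> DT

[indirect4]
GS -> CV
CV -> DT
TEMP -> DT
GC -> GS

[indirect5]
GS -> CV
CV -> DT
TEMP -> CV
TEMP -> GS
TEMP -> DT
GC -> GS
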