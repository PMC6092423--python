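# Cellular-component terms accepted by the "nuclear or cytosolic" filter.
# Editable: the exact term selection of any GO/PANTHER release is a moving
# target, so the allowed list ships as configuration rather than code.
allowed_terms:
  - nucleus
  - nucleoplasm
  - nucleolus
  - nuclear chromatin
  - chromatin
  - chromosome
  - nuclear body
  - nuclear speck
  - nuclear envelope
  - nuclear matrix
  - replication fork
  - spliceosomal complex
  - transcription factor complex
  - histone methyltransferase complex
  - ESC/E(Z) complex
  - PcG protein complex
  - PRC1 complex
  - cytosol
  - cytoplasm
  - cytoplasmic stress granule
  - cytoplasmic ribonucleoprotein granule
  - ribosome
  - proteasome complex
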