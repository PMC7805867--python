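# Default neuron exclusion list for the hermaphrodite somatic connectome.
#
# Pharyngeal neurons form a nearly self-contained nervous system of their
# own and are excluded from somatic-network analyses.  The 20 names below
# follow the classical pharynx anatomy literature (Albertson & Thomson);
# edit or replace this file if that set is revised.
I1L
I1R
I2L
I2R
I3
I4
I5
I6
M1
M2L
M2R
M3L
M3R
M4
M5
MCL
MCR
MI
NSML
NSMR
# Neurons without obvious connections in the reference wiring data:
VC6
CANR
CANL
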