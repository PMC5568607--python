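# Sezerman reduced alphabet, 11 groups — as printed in the source table,
# which lists 21 letters with T twice (…ST, A, G, TWC…).  This variant keeps
# T in the ST group and reads the ninth group as WC.  See sez-lit.yaml for
# the alternative resolution following the literature.
name: sez-table
groups:
  - IVLM
  - RK
  - H
  - DE
  - QN
  - ST
  - A
  - G
  - WC
  - YF
  - P
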