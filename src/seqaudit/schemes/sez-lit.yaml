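# Sezerman reduced alphabet, 11 groups — literature variant (H grouped with
# the basics RK; W and C as singletons).  Alternative resolution of the
# garbled printed row in sez-table.yaml.
name: sez-lit
groups:
  - IVLM
  - RKH
  - DE
  - QN
  - ST
  - A
  - G
  - W
  - C
  - YF
  - P
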