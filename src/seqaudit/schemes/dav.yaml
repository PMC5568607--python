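# Davies random reduced alphabet, 9 groups.
name: dav
groups:
  - SG
  - D
  - VIA
  - RQN
  - K
  - PWH
  - YC
  - LEM
  - FT
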