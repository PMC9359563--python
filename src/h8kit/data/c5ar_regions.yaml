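# Region annotation for the two human C5a receptors, UniProt numbering
# (P21730 = C5aR1, Q9P296 = C5aR2), inclusive spans.
#
# Boundaries are anchored on the functionally assigned residues of C5aR1
# (W213/P214 at position 5.50 in TM5, F254-Y258 'FWLPY' in TM6, N296-Y300
# 'NPIIY' closing TM7, the H8-forming residues L315/L319/V322/L323 and the
# crystal-structure numbering offset that places T324/E325 at the H8
# C-terminus) and on the receptor-vs-receptor alignment: ICL3 is drawn to
# span the block that is 12 residues in C5aR1 and 7 in C5aR2, ICL4 (the
# TM7-to-H8 connector) the block shorter by 3 residues in C5aR2.  Loop
# boundaries at the fuzzy TM5/ICL3/TM6 junctions are approximate and
# user-overridable; helix ends in these receptors genuinely fray.
P21730:
  N-term: [1, 37]
  TM1: [38, 61]
  ICL1: [62, 73]
  TM2: [74, 94]
  ECL1: [95, 108]
  TM3: [109, 130]
  ICL2: [131, 150]
  TM4: [151, 171]
  ECL2: [172, 199]
  TM5: [200, 233]
  ICL3: [234, 245]
  TM6: [246, 270]
  ECL3: [271, 279]
  TM7: [280, 300]
  ICL4: [301, 314]
  H8: [315, 324]
  C-term: [325, 350]
Q9P296:
  N-term: [1, 35]
  TM1: [36, 59]
  ICL1: [60, 71]
  TM2: [72, 92]
  ECL1: [93, 106]
  TM3: [107, 128]
  ICL2: [129, 148]
  TM4: [149, 169]
  ECL2: [170, 197]
  TM5: [198, 229]
  ICL3: [230, 236]
  TM6: [237, 261]
  ECL3: [262, 270]
  TM7: [271, 291]
  ICL4: [292, 302]
  H8: [303, 312]
  C-term: [313, 337]
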