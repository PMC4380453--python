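# Default SH3 phage-display library: uniform relative abundance over the
# SH3 domains handled in this package's bundled examples.  Crk(II) and
# CrkL(II) are excluded by default because these atypical SH3 domains are
# prone to affinity-independent selection and cause false positives.
library_id: full-default
domains:
  - AHI1
  - ArgBP2(II)
  - Btk
  - CIP4
  - Eps8L1
  - Eve-1(I)
  - FBP17
  - Fyn
  - Grb2(I)
  - Grb2(II)
  - Hck
  - Itk
  - Lck
  - Lyn
  - NCF1(I)
  - Nck(I)
  - Nephrocystin
  - OSTF1
  - PACSIN2
  - PACSIN3
  - RIMBP1(III)
  - RIMBP2(III)
  - RIMBP3(III)
  - SH3GL1P2
  - SNX18
  - SNX33
  - SNX9
  - Src
  - Tec
  - Tks5(I)
  - Tks5(V)
  - TOCA1
  - ZDHHC6
  - endophilin-A1
  - endophilin-A2
  - intersectin1(III)
  - intersectin2(III)
  - p85a
excluded:
  - Crk(II)
  - CrkL(II)
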