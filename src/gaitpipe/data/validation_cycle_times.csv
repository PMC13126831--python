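subject,group,reference_s,proposed_s
Subject 1,JIA,0.95,0.98
Subject 3,JIA,1.00,1.00
Subject 4,JIA,0.86,0.88
Subject 5,JIA,1.00,1.02
Subject 6,JIA,1.06,1.08
Subject 10,JIA,1.02,1.03
Subject 2,TD,1.09,1.08
Subject 7,TD,0.98,1.00
Subject 8,TD,0.99,0.94
Subject 9,TD,1.00,1.02
Subject 11,TD,0.94,0.97
Subject 12,TD,1.06,1.06
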