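gene_symbol
RAB5A
RAB7A
RAB11A
RAB27A
SEC23A
SEC24D
SEC61A1
ARF1
ARF6
SAR1A
COPA
COPB1
COPB2
CLTC
CLTA
AP1B1
AP2M1
AP2A1
VAMP3
VAMP7
VAMP8
SNAP23
SNAP29
STX4
STX6
STXBP1
NSF
NAPA
SCAMP1
SORT1
M6PR
LAMP1
LAMP2
TFRC
CAV1
CAVIN1
EHD1
DNM2
MYO5A
KIF5B
DCTN1
ACTB
ACTG1
CD74
CLU
MARCO
MSR1
GOLGA2
GOSR1
YKT6
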