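USP1
USP2
USP3
USP4
USP5
USP6
USP7
USP8
USP9X
USP9Y
USP10
USP11
USP12
USP13
USP14
USP15
USP16
USP18
USP19
USP20
USP21
USP22
USP24
USP25
USP26
USP27X
USP28
USP29
USP30
USP31
USP32
USP33
USP34
USP35
USP36
USP37
USP38
USP39
USP40
USP41
USP42
USP43
USP44
USP45
USP46
USP47
USP48
USP49
USP50
USP51
USP53
USP54
CYLD
USPL1
UCHL1
UCHL3
UCHL5
BAP1
OTUB1
OTUB2
OTUD1
OTUD3
OTUD4
OTUD5
OTUD6A
OTUD6B
OTUD7A
OTUD7B
ALG13
OTULIN
VCPIP1
ZRANB1
TNFAIP3
YOD1
ATXN3
ATXN3L
JOSD1
JOSD2
STAMBP
STAMBPL1
BRCC3
COPS5
COPS6
EIF3F
EIF3H
MPND
MYSM1
PSMD7
PSMD14
MINDY1
MINDY2
MINDY3
MINDY4
ZUP1
USP17L2
USP17L5
USP17L24
PAN2
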