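gene	species	rank	gene_id
DMI1	Mt	1	Medtr2g005620
DMI1	Ca	1	Ca_00033
DMI1	Lj	1	Lj6.CM0508.260.r2.m
DMI1	Cc	1	C.cajan_17266
DMI1	Cc	2	C.cajan_11017
DMI1	Pv	1	Phvulv091019046m
DMI1	Gm	1	Glyma12g28860
DMI1	Gm	2	Glyma16g00500
DMI1	Gm	3	Glyma19g45310
DMI2	Mt	1	Medtr5g032400
DMI2	Ca	1	Ca_11537
DMI2	Ca	2	Ca_17066
DMI2	Lj	1	Lj2.CM0177.340.r2.m
DMI2	Cc	1	C.cajan_12295
DMI2	Pv	1	Phvulv091027352m
DMI2	Gm	1	Glyma09g33510
DMI2	Gm	2	Glyma01g02460
DMI3	Mt	1	Medtr8g047760
DMI3	Mt	2	Medtr5g009940
DMI3	Ca	1	Ca_15707
DMI3	Lj	1	Lj3.LjT02O17.60.r2.m
DMI3	Cc	1	C.cajan_46131
DMI3	Pv	1	Phvulv091013422m
DMI3	Gm	1	Glyma15g35070
DMI3	Gm	2	Glyma08g24360
DMI3	Gm	3	Glyma10g11020
ERN1	Mt	1	Medtr7g102550
ERN1	Mt	2	Medtr6g031080
ERN1	Ca	1	Ca_08232
ERN1	Lj	1	Lj1.CM0104.2670.r2.m
ERN1	Cc	1	C.cajan_08385
ERN1	Cc	2	C.cajan_16144
ERN1	Pv	1	Phvulv091004951m
ERN1	Gm	1	Glyma16g04410
ERN1	Gm	2	Glyma19g29000
ERN3	Mt	1	Medtr6g015110
ERN3	Mt	2	Medtr4g134350
ERN3	Ca	1	Ca_08582
ERN3	Lj	1	Lj4.CM0046.750.r2.a
ERN3	Cc	1	C.cajan_23330
ERN3	Pv	1	Phvulv091030938m
ERN3	Gm	1	Glyma08g12130
ERN3	Gm	2	Glyma05g29011
FLOT2	Mt	1	Medtr3g137870
FLOT2	Mt	2	Medtr1g099720
FLOT2	Cc	1	C.cajan_09162
FLOT2	Pv	1	Phvulv091009868m
FLOT2	Gm	1	Glyma06g06930
FLOT2	Gm	2	Glyma04g06830
IPD3	Mt	1	Medtr5g027010
IPD3	Ca	1	Ca_10616
IPD3	Lj	1	Lj2.CM0803.150.r2.m
IPD3	Cc	1	C.cajan_12408
IPD3	Pv	1	Phvulv091016359m
IPD3	Gm	1	Glyma01g35255
IPD3	Gm	2	Glyma09g34695
LIN	Mt	1	Medtr1g112060
LIN	Ca	1	Ca_08341
LIN	Lj	1	Lj5.CM0909.400.r2.m
LIN	Cc	1	C.cajan_22455
LIN	Pv	1	Phvulv091027173m
LIN	Gm	1	Glyma10g33851
LIN	Gm	2	Glyma12g29771
LYK3	Mt	1	Medtr5g093450
LYK3	Mt	2	Medtr5g093440
LYK3	Mt	3	Medtr5g093730
LYK3	Mt	4	Medtr5g093410
LYK3	Ca	1	Ca_10278
LYK3	Lj	1	Lj2.CM0545.250.r2.m
LYK3	Lj	2	Lj6.CM0041.460.r2.a
LYK3	Cc	1	C.cajan_09999
LYK3	Cc	2	C.cajan_15801
LYK3	Pv	1	Phvulv091021871m
LYK3	Gm	1	Glyma14g05060
LYK3	Gm	2	Glyma02g43860
LYK3	Gm	3	Glyma02g43850
LYR3	Mt	1	Medtr5g019000
LYR3	Ca	1	Ca_02085
LYR3	Lj	1	Lj2.CM0323.420.r2.d
LYR3	Cc	1	C.cajan_12623
LYR3	Pv	1	Phvulv091008254m
LYR3	Gm	1	Glyma11g06750
LYR3	Gm	2	Glyma01g38550
LYR3	Gm	3	Glyma02g06700
NFP	Mt	1	Medtr5g018990
NFP	Mt	2	Medtr8g093910
NFP	Ca	1	Ca_02086
NFP	Ca	2	Ca_16029
NFP	Lj	1	Lj2.CM0323.400.r2.d
NFP	Cc	1	C.cajan_12621
NFP	Pv	1	Phvulv091008306m
NFP	Gm	1	Glyma11g06740
NFP	Gm	2	Glyma01g38560
NIN	Mt	1	Medtr5g106690
NIN	Ca	1	Ca_09832
NIN	Lj	1	Lj2.CM0102.250.r2.m
NIN	Cc	1	C.cajan_33924
NIN	Cc	2	C.cajan_37712
NIN	Pv	1	Phvulv091031090m
NIN	Pv	2	Phvulv091004689m
NIN	Gm	1	Glyma06g00240
NIN	Gm	2	Glyma04g00210
NIN	Gm	3	Glyma02g48080
NRT1	Mt	1	Medtr5g093170
NRT1	Ca	1	Ca_10291
NRT1	Lj	1	Lj2.CM0826.350.r2.m
NRT1	Lj	2	Lj2.CM0826.370.r2.m
NRT1	Lj	3	Lj2.CM0545.330.r2.m
NRT1	Cc	1	C.cajan_09986
NRT1	Pv	1	Phvulv091021785m
NRT1	Gm	1	Glyma02g43740
NRT1	Gm	2	Glyma14g05170
NSP1	Mt	1	Medtr8g025000
NSP1	Mt	2	Medtr5g015580
NSP1	Mt	3	Medtr8g101580
NSP1	Ca	1	Ca_10004
NSP1	Lj	1	Lj3.CM0416.1260.r2.d
NSP1	Cc	1	C.cajan_27701
NSP1	Pv	1	Phvulv091018505m
NSP1	Pv	2	Phvulv091030806m
NSP1	Pv	3	Phvulv091007340m
NSP1	Gm	1	Glyma07g04430
NSP1	Gm	2	Glyma16g01020
NSP1	Gm	3	Glyma05g22460
NSP2	Mt	1	Medtr3g097800
NSP2	Mt	2	Medtr5g065380
NSP2	Ca	1	Ca_26279
NSP2	Ca	2	Ca_23494
NSP2	Lj	1	Lj1.CM1976.90.r2.m
NSP2	Cc	1	C.cajan_01355
NSP2	Cc	2	C.cajan_32376
NSP2	Pv	1	Phvulv091012665m
NSP2	Gm	1	Glyma04g43090
NSP2	Gm	2	Glyma06g11610
NSP2	Gm	3	Glyma13g02840
RRP1	Mt	1	Medtr1g074280
RRP1	Ca	1	Ca_26056
RRP1	Ca	2	Ca_19055
RRP1	Lj	1	Lj5.CM1077.650.r2.m
RRP1	Cc	1	C.cajan_33337
RRP1	Pv	1	Phvulv091005582m
RRP1	Gm	1	Glyma13g21080
RRP1	Gm	2	Glyma10g07190
SKL1	Mt	1	Medtr7g121800
SKL1	Ca	1	Ca_12043
SKL1	Lj	1	Lj1.CM0012.1100.r2.m
SKL1	Cc	1	C.cajan_45110
SKL1	Pv	1	Phvulv091008769m
SKL1	Gm	1	Glyma03g33850
SKL1	Gm	2	Glyma13g20810
SKL1	Gm	3	Glyma10g06610
SUNN	Mt	1	Medtr4g096420
SUNN	Mt	2	Medtr4g096400
SUNN	Ca	1	Ca_15399
SUNN	Ca	2	Ca_09375
SUNN	Cc	1	C.cajan_21258
SUNN	Cc	2	C.cajan_24880
SUNN	Cc	3	C.cajan_39327
SUNN	Lj	1	Lj3.CM0091.1690.r2.m
SUNN	Pv	1	Phvulv091015304m
SUNN	Gm	1	Glyma12g04390
SUNN	Gm	2	Glyma11g12186
N56	Mt	1	Medtr1g146810
N56	Ca	1	Ca_13985
N56	Ca	2	Ca_26114
N56	Lj	1	Lj5.CM0492.390.r2.m
N56	Lj	2	Lj1.CM0001.650.r2.m
N56	Lj	3	Lj1.CM0001.690.r2.m
N56	Lj	4	Lj1.CM0001.710.r2.m
N56	Cc	1	C.cajan_07899
N56	Cc	2	C.cajan_37827
N56	Cc	3	C.cajan_46126
N56	Pv	1	Phvulv091005854m
N56	Gm	1	Glyma10g44180
N56	Gm	2	Glyma20g38950
N56	Gm	3	Glyma13g12484
N56	Gm	4	Glyma19g29920
N56	Gm	5	Glyma19g29880
ENOD93	Mt	1	Medtr8g119590
ENOD93	Ca	1	Ca_06646
ENOD93	Cc	1	C.cajan_46055
ENOD93	Cc	2	C.cajan_26197
ENOD93	Cc	3	C.cajan_26199
ENOD93	Pv	1	Phvulv091017136m
ENOD93	Gm	1	Glyma06g24760
ENOD93	Gm	2	Glyma05g08400
ENOD93	Gm	3	Glyma17g12600
ENOD93	Gm	4	Glyma17g12610
ENOD93	Gm	5	Glyma05g08380
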