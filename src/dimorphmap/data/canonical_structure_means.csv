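structure,age_days,sex,absolute_mm3,relative_pct_brain
BNST,3,M,0.589,0.2810
BNST,3,F,0.583,0.2850
BNST,5,M,0.719,0.2800
BNST,5,F,0.724,0.2750
BNST,7,M,0.857,0.2810
BNST,7,F,0.850,0.2740
BNST,10,M,1.060,0.2780
BNST,10,F,1.010,0.2710
BNST,17,M,1.160,0.2760
BNST,17,F,1.110,0.2650
BNST,23,M,1.110,0.2740
BNST,23,F,1.060,0.2630
BNST,29,M,1.100,0.2700
BNST,29,F,1.050,0.2620
BNST,36,M,1.130,0.2690
BNST,36,F,1.060,0.2630
BNST,65,M,1.200,0.2770
BNST,65,F,1.120,0.2640
MPON,3,M,0.0856,0.0394
MPON,3,F,0.0844,0.0400
MPON,5,M,0.103,0.0397
MPON,5,F,0.102,0.0382
MPON,7,M,0.117,0.0400
MPON,7,F,0.115,0.0389
MPON,10,M,0.152,0.0396
MPON,10,F,0.147,0.0390
MPON,17,M,0.184,0.0399
MPON,17,F,0.178,0.0388
MPON,23,M,0.149,0.0393
MPON,23,F,0.146,0.0386
MPON,29,M,0.150,0.0383
MPON,29,F,0.146,0.0378
MPON,36,M,0.158,0.0380
MPON,36,F,0.152,0.0380
MPON,65,M,0.168,0.0386
MPON,65,F,0.158,0.0373
MeA,3,M,0.506,0.2420
MeA,3,F,0.490,0.2410
MeA,5,M,0.573,0.2440
MeA,5,F,0.578,0.2400
MeA,7,M,0.660,0.2450
MeA,7,F,0.653,0.2380
MeA,10,M,0.800,0.2440
MeA,10,F,0.764,0.2360
MeA,17,M,0.973,0.2440
MeA,17,F,0.933,0.2350
MeA,23,M,0.976,0.2450
MeA,23,F,0.938,0.2350
MeA,29,M,0.966,0.2430
MeA,29,F,0.917,0.2350
MeA,36,M,1.000,0.2430
MeA,36,F,0.930,0.2340
MeA,65,M,1.060,0.2430
MeA,65,F,0.983,0.2310
PAG,3,M,2.630,0.9740
PAG,3,F,2.580,0.9840
PAG,5,M,2.950,0.9830
PAG,5,F,2.980,0.9700
PAG,7,M,3.310,0.9750
PAG,7,F,3.310,0.9580
PAG,10,M,3.960,0.9590
PAG,10,F,3.860,0.9510
PAG,17,M,4.070,0.9700
PAG,17,F,3.990,0.9580
PAG,23,M,3.820,0.9620
PAG,23,F,3.770,0.9490
PAG,29,M,3.740,0.9580
PAG,29,F,3.670,0.9560
PAG,36,M,3.760,0.9400
PAG,36,F,3.690,0.9590
PAG,65,M,4.010,0.9240
PAG,65,F,3.970,0.9340
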