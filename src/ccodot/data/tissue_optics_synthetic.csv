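# units: mua mm^-1, musp mm^-1
# SYNTHETIC stand-in table: smooth monotone-cubic curve anchored to widely cited literature values; not a digitization of any single published compendium.
tissue,wavelength_nm,mua_per_mm,musp_per_mm
scalp,700,0.015204,0.8686
scalp,720,0.013030,0.8397
scalp,740,0.013309,0.8126
scalp,760,0.017280,0.7870
scalp,780,0.016829,0.7628
scalp,800,0.016400,0.7400
scalp,820,0.017417,0.7184
scalp,840,0.018921,0.6979
scalp,860,0.020129,0.6785
scalp,880,0.021223,0.6600
scalp,900,0.022262,0.6425
scalp,920,0.023554,0.6257
scalp,940,0.023811,0.6098
scalp,960,0.023995,0.5946
scalp,980,0.024400,0.5801
scalp,1000,0.024718,0.5662
skull,700,0.010754,1.0743
skull,720,0.009216,1.0444
skull,740,0.009413,1.0162
skull,760,0.012222,0.9895
skull,780,0.011903,0.9641
skull,800,0.011600,0.9400
skull,820,0.012320,0.9171
skull,840,0.013383,0.8952
skull,860,0.014238,0.8744
skull,880,0.015018,0.8545
skull,900,0.015765,0.8356
skull,920,0.016697,0.8174
skull,940,0.016904,0.8000
skull,960,0.017064,0.7833
skull,980,0.017387,0.7673
skull,1000,0.017654,0.7520
csf,700,0.003708,0.3207
csf,720,0.003178,0.3162
csf,740,0.003246,0.3119
csf,760,0.004215,0.3078
csf,780,0.004105,0.3038
csf,800,0.004000,0.3000
csf,820,0.004248,0.2963
csf,840,0.004615,0.2928
csf,860,0.004914,0.2893
csf,880,0.005217,0.2860
csf,900,0.005544,0.2828
csf,920,0.005968,0.2798
csf,940,0.006176,0.2768
csf,960,0.006403,0.2739
csf,980,0.006721,0.2711
csf,1000,0.007053,0.2683
gm,700,0.016687,0.9860
gm,720,0.014301,0.9532
gm,740,0.014607,0.9224
gm,760,0.018966,0.8933
gm,780,0.018471,0.8659
gm,800,0.018000,0.8400
gm,820,0.019117,0.8155
gm,840,0.020767,0.7922
gm,860,0.022091,0.7702
gm,880,0.023277,0.7492
gm,900,0.024390,0.7293
gm,920,0.025767,0.7103
gm,940,0.025994,0.6922
gm,960,0.026126,0.6749
gm,980,0.026488,0.6584
gm,1000,0.026739,0.6427
wm,700,0.015482,1.3783
wm,720,0.013268,1.3362
wm,740,0.013552,1.2966
wm,760,0.017596,1.2591
wm,780,0.017137,1.2236
wm,800,0.016700,1.1900
wm,820,0.017736,1.1581
wm,840,0.019267,1.1278
wm,860,0.020496,1.0990
wm,880,0.021608,1.0716
wm,900,0.022661,1.0454
wm,920,0.023969,1.0204
wm,940,0.024221,0.9966
wm,960,0.024395,0.9738
wm,980,0.024792,0.9519
wm,1000,0.025097,0.9310
scalp_skull,700,0.012979,0.9729
scalp_skull,720,0.011123,0.9432
scalp_skull,740,0.011361,0.9152
scalp_skull,760,0.014751,0.8888
scalp_skull,780,0.014366,0.8637
scalp_skull,800,0.014000,0.8400
scalp_skull,820,0.014869,0.8175
scalp_skull,840,0.016152,0.7961
scalp_skull,860,0.017183,0.7758
scalp_skull,880,0.018120,0.7564
scalp_skull,900,0.019014,0.7379
scalp_skull,920,0.020126,0.7203
scalp_skull,940,0.020357,0.7035
scalp_skull,960,0.020529,0.6874
scalp_skull,980,0.020894,0.6719
scalp_skull,1000,0.021186,0.6572
brain,700,0.016687,0.9860
brain,720,0.014301,0.9532
brain,740,0.014607,0.9224
brain,760,0.018966,0.8933
brain,780,0.018471,0.8659
brain,800,0.018000,0.8400
brain,820,0.019117,0.8155
brain,840,0.020767,0.7922
brain,860,0.022091,0.7702
brain,880,0.023277,0.7492
brain,900,0.024390,0.7293
brain,920,0.025767,0.7103
brain,940,0.025994,0.6922
brain,960,0.026126,0.6749
brain,980,0.026488,0.6584
brain,1000,0.026739,0.6427
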