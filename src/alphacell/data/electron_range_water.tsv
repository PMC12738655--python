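# CSDA range of electrons in liquid water (1 g/cm^3), transcribed from
# standard ESTAR-water values at sparse nodes; log-log interpolation.
# Used only to decide whether a secondary electron deposits locally
# (range below the local-deposit cut, default 1 um) or escapes the world.
# energy_mev	range_um
0.001	0.05
0.002	0.16
0.003	0.31
0.005	0.79
0.007	1.40
0.010	2.52
0.015	5.1
0.020	8.6
0.030	17.6
0.050	43.2
0.070	78.0
0.100	143.0
0.200	448.0
0.300	843.0
0.500	1766.0
0.700	2800.0
1.000	4367.0
2.000	9785.0
3.000	15140.0
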