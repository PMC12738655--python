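# Electronic stopping power of alpha particles in liquid water (1 g/cm^3).
# Bethe stopping (I = 75 eV, Z/A = 0.5551) above 2 MeV, where it matches the
# ICRU-49/ASTAR evaluation to ~1-2%, joined smoothly through the empirical
# Bragg-peak region (~226 keV/um near 0.7 MeV) at low energy. Anchors
# reproduced: ~88 keV/um at 5.3 MeV; CSDA range ~39 um (5.3 MeV),
# ~40 um (5.5 MeV). Log-log interpolation between nodes; below the first
# node the remaining energy is deposited locally.
# energy_mev	stopping_kev_per_um
0.10	130.0
0.15	162.0
0.20	185.0
0.30	210.0
0.40	220.0
0.50	225.0
0.60	226.5
0.70	226.0
0.80	222.0
0.90	216.0
1.00	209.0
1.25	197.0
1.50	188.0
1.75	179.0
2.00	170.5
2.50	147.7
3.00	130.9
3.50	117.8
4.00	107.3
4.50	98.9
5.00	91.6
5.50	85.6
6.00	80.3
6.50	75.7
7.00	71.7
7.50	68.1
8.00	64.9
8.50	62.0
9.00	59.4
9.50	57.0
10.00	54.8
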