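# alphacell decay-chain data, schema alphacell-decay-v1
#
# One record per nuclide. Branch probabilities are fractions that sum to 1
# per nuclide. Emission energies are in MeV. For `beta` emissions the
# energy is the MEAN beta energy; the chain sampler draws a single energy
# from an exponential surrogate with that mean. Alpha recoils are NOT
# listed: the sampler pairs every alpha with a recoil of the daughter
# nucleus, E_recoil = E_alpha * m_alpha / m_daughter (mass numbers).
#
# Alpha energies and branching ratios transcribed from standard evaluated
# nuclear data (ENSDF / ICRP-107); minor alpha lines (< ~7% of a nuclide's
# alpha intensity) folded into the listed lines and weights renormalised.
# Gammas are carried for bookkeeping only (they escape the 30 um world).
schema: alphacell-decay-v1
nuclides:
  # ---- At-211 chain (1 alpha per parent decay) -------------------------
  At-211:
    half_life_s: 2.597e4
    branches:
      - probability: 0.418
        mode: alpha
        daughter: Bi-207
        emissions:
          - {kind: alpha, energy_mev: 5.8695}
      - probability: 0.582
        mode: electron_capture
        daughter: Po-211
        emissions: []
  Po-211:
    half_life_s: 0.516
    branches:
      - probability: 1.0
        mode: alpha
        daughter: Pb-207
        emissions:
          - {kind: alpha, energy_mev: 7.4503}
  Bi-207:
    half_life_s: 9.95e8          # 31.5 y; retained by default (truncatable)
    branches:
      - probability: 1.0
        mode: electron_capture
        daughter: Pb-207
        emissions:
          - {kind: gamma, energy_mev: 0.5697}
          - {kind: gamma, energy_mev: 1.0637}
          - {kind: electron, energy_mev: 0.9756}   # K conversion line
  Pb-207:
    half_life_s: .inf
    stable: true

  # ---- Pb-212 chain (1 alpha per parent decay) -------------------------
  Pb-212:
    half_life_s: 3.8304e4
    branches:
      - probability: 1.0
        mode: beta
        daughter: Bi-212
        emissions:
          - {kind: beta, energy_mev: 0.102}
          - {kind: gamma, energy_mev: 0.2386}
  Bi-212:
    half_life_s: 3633.0
    branches:
      - probability: 0.2590
        mode: alpha
        daughter: Tl-208
        emissions:
          - {kind: alpha, energy_mev: 6.0510}
      - probability: 0.1004
        mode: alpha
        daughter: Tl-208
        emissions:
          - {kind: alpha, energy_mev: 6.0898}
      - probability: 0.6406
        mode: beta
        daughter: Po-212
        emissions:
          - {kind: beta, energy_mev: 0.771}
          - {kind: gamma, energy_mev: 0.7272}
  Po-212:
    half_life_s: 2.99e-7
    branches:
      - probability: 1.0
        mode: alpha
        daughter: Pb-208
        emissions:
          - {kind: alpha, energy_mev: 8.7849}
  Tl-208:
    half_life_s: 183.2
    branches:
      - probability: 1.0
        mode: beta
        daughter: Pb-208
        emissions:
          - {kind: beta, energy_mev: 0.560}
          - {kind: gamma, energy_mev: 2.6145}
          - {kind: gamma, energy_mev: 0.5831}
  Pb-208:
    half_life_s: .inf
    stable: true

  # ---- Ra-223 chain (4 alphas per parent decay) ------------------------
  Ra-223:
    half_life_s: 9.8755e5
    branches:
      - probability: 0.5515
        mode: alpha
        daughter: Rn-219
        emissions:
          - {kind: alpha, energy_mev: 5.7162}
          - {kind: gamma, energy_mev: 0.2699}
      - probability: 0.2542
        mode: alpha
        daughter: Rn-219
        emissions:
          - {kind: alpha, energy_mev: 5.6067}
      - probability: 0.0998
        mode: alpha
        daughter: Rn-219
        emissions:
          - {kind: alpha, energy_mev: 5.7470}
      - probability: 0.0945
        mode: alpha
        daughter: Rn-219
        emissions:
          - {kind: alpha, energy_mev: 5.5398}
  Rn-219:
    half_life_s: 3.96
    branches:
      - probability: 0.7955
        mode: alpha
        daughter: Po-215
        emissions:
          - {kind: alpha, energy_mev: 6.8193}
          - {kind: gamma, energy_mev: 0.2712}
      - probability: 0.1293
        mode: alpha
        daughter: Po-215
        emissions:
          - {kind: alpha, energy_mev: 6.5526}
      - probability: 0.0752
        mode: alpha
        daughter: Po-215
        emissions:
          - {kind: alpha, energy_mev: 6.4250}
  Po-215:
    half_life_s: 1.781e-3
    branches:
      - probability: 1.0
        mode: alpha
        daughter: Pb-211
        emissions:
          - {kind: alpha, energy_mev: 7.3861}
  Pb-211:
    half_life_s: 2166.0
    branches:
      - probability: 1.0
        mode: beta
        daughter: Bi-211
        emissions:
          - {kind: beta, energy_mev: 0.447}
          - {kind: gamma, energy_mev: 0.8319}
  Bi-211:
    half_life_s: 128.4
    branches:
      - probability: 0.8353
        mode: alpha
        daughter: Tl-207
        emissions:
          - {kind: alpha, energy_mev: 6.6229}
          - {kind: gamma, energy_mev: 0.3513}
      - probability: 0.1619
        mode: alpha
        daughter: Tl-207
        emissions:
          - {kind: alpha, energy_mev: 6.2782}
      - probability: 0.0028
        mode: beta
        daughter: Po-211
        emissions:
          - {kind: beta, energy_mev: 0.172}
  Tl-207:
    half_life_s: 286.2
    branches:
      - probability: 1.0
        mode: beta
        daughter: Pb-207
        emissions:
          - {kind: beta, energy_mev: 0.493}

  # ---- Ac-225 chain (4 alphas per parent decay) ------------------------
  Ac-225:
    half_life_s: 8.5709e5
    branches:
      - probability: 0.655
        mode: alpha
        daughter: Fr-221
        emissions:
          - {kind: alpha, energy_mev: 5.8301}
      - probability: 0.234
        mode: alpha
        daughter: Fr-221
        emissions:
          - {kind: alpha, energy_mev: 5.7924}
      - probability: 0.111
        mode: alpha
        daughter: Fr-221
        emissions:
          - {kind: alpha, energy_mev: 5.7323}
  Fr-221:
    half_life_s: 288.0
    branches:
      - probability: 0.8467
        mode: alpha
        daughter: At-217
        emissions:
          - {kind: alpha, energy_mev: 6.3414}
          - {kind: gamma, energy_mev: 0.2183}
      - probability: 0.1533
        mode: alpha
        daughter: At-217
        emissions:
          - {kind: alpha, energy_mev: 6.1264}
  At-217:
    half_life_s: 3.23e-2
    branches:
      - probability: 1.0
        mode: alpha
        daughter: Bi-213
        emissions:
          - {kind: alpha, energy_mev: 7.0669}
  Bi-213:
    half_life_s: 2736.6
    branches:
      - probability: 0.9791
        mode: beta
        daughter: Po-213
        emissions:
          - {kind: beta, energy_mev: 0.435}
          - {kind: gamma, energy_mev: 0.4405}
      - probability: 0.0209
        mode: alpha
        daughter: Tl-209
        emissions:
          - {kind: alpha, energy_mev: 5.8750}
  Po-213:
    half_life_s: 3.72e-6
    branches:
      - probability: 1.0
        mode: alpha
        daughter: Pb-209
        emissions:
          - {kind: alpha, energy_mev: 8.3762}
  Tl-209:
    half_life_s: 129.7
    branches:
      - probability: 1.0
        mode: beta
        daughter: Pb-209
        emissions:
          - {kind: beta, energy_mev: 0.660}
          - {kind: gamma, energy_mev: 1.5670}
  Pb-209:
    half_life_s: 1.1628e4
    branches:
      - probability: 1.0
        mode: beta
        daughter: Bi-209
        emissions:
          - {kind: beta, energy_mev: 0.198}
  Bi-209:
    half_life_s: .inf            # alpha-decays with t1/2 ~ 2e19 y; stable here
    stable: true
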