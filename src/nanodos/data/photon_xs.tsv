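# Photon interaction coefficients for liquid water, v1, valid 10-150 keV.
# Photoelectric and coherent (Rayleigh) mass attenuation coefficients are a
# compact set of reference points interpolated log-log by the PhotonModel;
# the incoherent (Compton) channel is computed analytically as the
# Klein-Nishina cross section per electron times the electron density (the
# free-electron approximation, good to a few percent above ~20 keV).
# columns: E_keV mu_photoelectric_cm2_g mu_rayleigh_cm2_g
10    4.944    0.300
15    1.374    0.155
20    0.544    0.095
30    0.146    0.047
40    0.0573   0.028
50    0.0277   0.0185
60    0.0153   0.0133
80    0.00577  0.0080
100   0.00276  0.0055
150   0.00075  0.0027
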