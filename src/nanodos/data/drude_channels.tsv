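# Drude channel parameters for the liquid-water energy-loss function, v1.
# Semiempirical reconstruction in the optical-data Drude family: five discrete
# electronic excitations (A1B1, B1A1, Rydberg A+B, Rydberg C+D, diffuse bands)
# and five ionization shells (1b1, 3a1, 1b2, 2a1, O K-shell).
# Constraints used when the set was frozen: lowest excitation threshold at
# 8.23 eV; optical ELF peak at ~21 eV (this set: 21.3 eV, height 1.30);
# f-sum within 5% of (pi/2) Ep^2 for water (ratio 1.038); mean excitation
# energy from the f-sum log-moment close to the Bragg-additivity value for
# water (this set: 63.2 eV vs 68.9 eV).
# columns: kind label E_k_eV f_k gamma_k_eV B_k_eV dispersion
excitation A1B1     8.23  0.0070   1.6   -      1.0
excitation B1A1    10.00  0.0090   2.0   -      1.0
excitation RydAB   11.24  0.0110   2.5   -      1.0
excitation RydCD   12.61  0.0160   3.0   -      1.0
excitation diffuse 13.77  0.0260   3.5   -      1.0
ionization 1b1     16.90  0.0500   5.0  10.79   1.0
ionization 3a1     18.60  0.0700   6.5  13.39   1.0
ionization 1b2     22.30  0.4400   8.5  16.05   1.0
ionization 2a1     55.00  0.2300  60.0  32.30   1.0
ionization K      560.00  0.1800 300.0 539.70   1.0
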