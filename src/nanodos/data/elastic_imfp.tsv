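# Elastic inverse mean free path of electrons in liquid water, v1.
# Anchor points for log-log interpolation; the screened-Rutherford angular
# model in nanodos.elastic supplies the angular distribution.  The table has
# the same role and format a partial-wave elastic table would have, so a
# higher-fidelity table can be dropped in without code changes.
# columns: T_eV Lambda_el_per_nm
8.23   2.5
10     2.8
20     3.5
30     3.6
50     3.2
100    2.2
200    1.4
500    0.75
1000   0.45
2000   0.26
5000   0.12
10000  0.065
30000  0.024
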