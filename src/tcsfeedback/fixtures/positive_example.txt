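# Positive-feedback example parameter set (open-loop gain > 0 at k_ph = 0.1/s).
# Units: s, uM. One "key: value" pair per line.
k_ap: 8.408
k_ad: 0.004832
k_pt: 1.392
k_tp: 0.05183
k_b: 0.07871
k_d: 0.001172
k_b1: 2.395
k_d1: 0.002223
k_RRPdm: 2.665
k_RRPmd: 7.421
k_txn: 6.604e-4
k_SKtsn: 0.005240
tsn_mult: 6.190
k_txnbasal: 3.413e-5
K_mDS: 0.06276
K_m: 0.003958
k_mRNAdeg: 0.007446
k_exp: 3.452e-6
K_mexp: 4.101e-4
k_exd: 5.017e-6
K_mexd: 1.661e-4
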