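# Negative-feedback example parameter set (open-loop gain < 0 at k_ph = 0.1/s).
# Units: s, uM. One "key: value" pair per line.
k_ap: 0.1706
k_ad: 9.786
k_pt: 0.2028
k_tp: 0.1368
k_b: 2.314
k_d: 0.9237
k_b1: 6.261
k_d1: 0.001825
k_RRPdm: 9.794
k_RRPmd: 0.1411
k_txn: 2.115e-5
k_SKtsn: 0.04708
tsn_mult: 5.616
k_txnbasal: 2.245e-6
K_mDS: 0.01224
K_m: 0.004298
k_mRNAdeg: 0.001383
k_exp: 0.02668
K_mexp: 0.1361
k_exd: 4.218e-5
K_mexd: 1.388
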