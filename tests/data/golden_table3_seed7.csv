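algorithm,n_positive,sensitivity,spec,ppv,npv
1,54,"98.0 (89.6, 100.0)","97.5 (93.6, 99.3)","92.6 (82.1, 97.9)","99.4 (96.5, 100.0)"
3,38,"74.5 (60.4, 85.7)","100.0 (97.7, 100.0)","100.0 (90.7, 100.0)","92.4 (87.4, 95.9)"
5,91,"98.1 (90.1, 100.0)","76.8 (69.6, 83.1)","58.2 (47.4, 68.5)","99.2 (95.7, 100.0)"
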