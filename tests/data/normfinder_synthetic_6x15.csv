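mirna,CTR-01,CTR-02,CTR-03,CTR-04,CTR-05,D-01,D-02,D-03,D-04,D-05,DME-01,DME-02,DME-03,DME-04,DME-05
cand-1,22.871,24.0239,24.4338,24.5902,24.3322,23.1631,23.6589,23.9999,24.1127,24.095,23.4775,23.7248,22.9821,24.139,23.7298
cand-2,24.6676,26.8048,27.2695,27.6048,26.5166,25.844,26.442,26.0401,26.3463,26.5401,25.9238,26.008,25.4922,26.8464,25.9941
cand-3,26.7481,27.9407,28.1478,28.5199,28.1789,26.8606,28.1099,28.1427,28.1269,27.7004,28.5975,28.2839,27.4583,29.6475,28.2687
cand-4,22.0967,23.5281,24.0966,24.6818,24.0472,22.3161,23.0223,23.3157,23.4404,23.3345,22.9917,22.5863,22.8205,23.9646,23.0388
cand-5,28.5935,29.9609,30.4055,30.3503,30.5634,28.6647,29.075,29.4752,29.4131,29.5554,29.9541,29.106,28.9835,30.4184,29.7966
cand-6,23.8132,25.0708,25.2196,25.4414,25.3975,24.3713,24.662,25.1689,24.6978,24.7081,24.3987,24.2985,23.6927,25.6353,25.3313
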