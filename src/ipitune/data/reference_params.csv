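species,individual_id,a,tau_b,c,tau_d,peak_ipi_ms
melanogaster,Average,0.2017,83.9797,1.8644,3.898,21.6406
melanogaster,1,0.2013,84.0215,1.7965,3.8674,21.3527
melanogaster,2,0.2009,85.0849,2.1112,4.0494,22.9484
melanogaster,3,0.2021,83.7082,1.9231,3.8965,21.7417
melanogaster,4,0.2024,83.0712,1.5545,3.7737,20.2818
melanogaster,5,0.2014,84.89,2.2657,4.1005,23.4844
melanogaster,6,0.2023,83.3108,1.8304,3.854,21.3208
melanogaster,7,0.2011,84.3212,1.6926,3.847,21.0305
melanogaster,8,0.2013,84.4185,2.0044,3.9433,22.1793
melanogaster,9,0.2024,82.8497,1.4995,3.7473,20.0106
melanogaster,10,0.2017,83.7572,1.7758,3.8357,21.1392
melanogaster,11,0.2013,84.9794,2.1943,4.1031,23.3643
melanogaster,12,0.202,83.6037,1.806,3.8435,21.2328
simulans,Average,0.2084,85.8339,3.5893,4.0434,25.0429
simulans,1,0.2085,85.0732,3.4764,3.9527,24.3868
simulans,2,0.2088,85.0319,3.3028,3.9362,24.0791
simulans,3,0.2081,86.4459,3.7934,4.1125,25.6852
simulans,4,0.2086,85.8512,3.5614,4.039,24.9814
simulans,5,0.2083,86.1206,3.622,4.0441,25.0961
simulans,6,0.2079,85.981,3.6284,4.0277,25.0185
simulans,7,0.2074,87.1292,3.6964,4.0882,25.4785
simulans,8,0.2083,85.8879,3.5869,4.0156,24.8923
simulans,9,0.2083,85.5537,3.605,4.0428,25.0496
simulans,10,0.2085,85.3784,3.5757,4.0142,24.8486
simulans,11,0.2088,85.4958,3.68,4.0551,25.1912
simulans,12,0.2082,85.7921,3.6087,4.0395,25.0463
simulans,13,0.2079,86.7457,3.7893,4.1084,25.6735
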