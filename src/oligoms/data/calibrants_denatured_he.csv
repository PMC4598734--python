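protein,charge,mass,ccs_ref
ubiquitin,9,8565.8,1649
ubiquitin,10,8565.8,1732
ubiquitin,11,8565.8,1802
myoglobin,15,16951.5,3313
myoglobin,16,16951.5,3489
myoglobin,17,16951.5,3606
myoglobin,18,16951.5,3682
myoglobin,19,16951.5,3727
myoglobin,20,16951.5,3805
myoglobin,21,16951.5,3882
myoglobin,22,16951.5,3954
cytochrome_c,11,12360.1,2303
cytochrome_c,12,12360.1,2335
cytochrome_c,13,12360.1,2391
cytochrome_c,14,12360.1,2473
cytochrome_c,15,12360.1,2579
cytochrome_c,16,12360.1,2679
cytochrome_c,17,12360.1,2723
cytochrome_c,18,12360.1,2766
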