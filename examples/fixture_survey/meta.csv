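site_id,group,elevation_m,aspect,mat_c
1,G1,2442.0,W,14.0
2,G2,2508.0,W,14.0
7,G3,2614.0,SW,14.0
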