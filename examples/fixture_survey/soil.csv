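site_id,depth_top_cm,depth_bottom_cm,sp_pct,sand_pct,silt_pct,clay_pct,ph,ec_dsm
1,0.0,25.0,37.66492844969966,41.198279331113916,32.684396907992394,26.117323760893708,7.763569738901824,0.7600887598047169
1,25.0,50.0,38.66492844969966,39.255459918987604,33.65580661405555,27.088733466956864,7.813569738901824,0.810088759804717
2,0.0,25.0,35.948032100269245,44.63804225248044,30.86594485908675,24.496012888432816,7.698073352945295,1.1503929823036412
2,25.0,50.0,36.948032100269245,42.58194915920314,31.893991405725398,25.52405943507146,7.748073352945296,1.200392982303641
7,0.0,25.0,29.723801950674165,54.99123933171059,23.84467408241673,21.16408658587269,7.764063466878502,1.8252721910927412
7,25.0,50.0,30.723801950674165,53.002129122993594,24.839229186775228,22.158641690231185,7.814063466878503,1.875272191092741
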