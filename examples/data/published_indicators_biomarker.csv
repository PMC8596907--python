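method,bias_ratio,bias_slope,relative_error,cv_pct,precision,resolution
CqMAN,2469.0003,0.0182,0.2416,7.20,0.0020,1.9222
Cy0,2594.5631,0.0000,0.1050,9.62,0.0064,1.9213
LinRegPCR,3891.3018,0.0523,0.3117,9.64,0.0064,1.9051
PCR-Miner,6167.5939,0.0561,0.2287,9.63,0.0062,1.9156
5PSM,6041.4519,0.0999,0.6939,12.89,0.0096,3.0166
DART,5233.9256,0.0840,0.5727,17.98,0.0140,2.8630
FPLM,4814.3920,0.0745,0.5357,21.34,0.0182,3.1956
FPK-PCR,8536.6094,0.0669,0.3592,25.12,0.0339,5.8404
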