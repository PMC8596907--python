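method,bias_ratio,bias_slope,relative_error,cv_pct,precision,resolution
CqMAN,0.0000,0.0000,0.0873,10.86,0.0025,2.0132
Cy0,0.0000,0.0000,0.0935,10.42,0.0027,2.1344
LinRegPCR,0.0008,0.0869,0.4126,11.32,0.0039,1.5326
PCR-Miner,0.0001,0.0054,0.1434,12.39,0.0057,2.0524
5PSM,0.0057,0.2633,2.5536,41.40,0.0409,7.0584
DART,0.0022,0.1723,1.0169,39.86,0.0308,7.1726
FPLM,0.0008,0.0617,0.6724,50.71,0.0609,7.4493
FPK-PCR,0.0007,0.1672,0.5012,29.55,0.0236,7.8181
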