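acid,variety,stage,mean,sd,n
OA,AMT,S1,1.3182,0.22,3
OA,AMT,S2,0.7615,0.44,3
OA,AMT,S3,0.6233,0.11,3
OA,AMT,S4,0.1669,0.0085,3
OA,DSHS,S1,0.8982,0.12,3
OA,DSHS,S2,0.8406,0.040,3
OA,DSHS,S3,0.2305,0.048,3
OA,DSHS,S4,0.1959,0.0084,3
MA,AMT,S1,6.543,0.35,3
MA,AMT,S2,2.195,0.64,3
MA,AMT,S3,6.232,0.39,3
MA,AMT,S4,4.310,0.50,3
MA,DSHS,S1,3.045,0.11,3
MA,DSHS,S2,2.153,0.16,3
MA,DSHS,S3,2.920,0.034,3
MA,DSHS,S4,2.178,0.093,3
CA,AMT,S1,1.927,0.15,3
CA,AMT,S2,1.443,0.15,3
CA,AMT,S3,1.606,0.19,3
CA,AMT,S4,1.574,0.082,3
CA,DSHS,S1,1.412,0.16,3
CA,DSHS,S2,1.116,0.11,3
CA,DSHS,S3,1.265,0.12,3
CA,DSHS,S4,0.7402,0.068,3
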