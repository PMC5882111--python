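n_alternatives,coherence,mean_rt_ms,n_trials
2,3.2,592.2383918898004,6461
2,6.4,552.3226232976332,7563
2,12.8,527.3420151220071,8729
2,25.6,465.84232277370756,9691
2,51.2,434.7588686241106,9979
4,3.2,661.5679072015466,4138
4,6.4,592.7509386733416,5593
4,12.8,539.2741804965026,7291
4,25.6,474.0465441338323,9086
4,51.2,433.55538298087623,9883
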