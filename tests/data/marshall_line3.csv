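case,county_id,count,population,exp_local_mean,exp_weight,exp_smoothed
spec,0,1,100,0.01,0.0,0.01
spec,1,10,1000,0.01,0.0,0.01
spec,2,2,200,0.01,0.0,0.01
uneven,0,3,100,0.011818181818181818,0.08917197452229296,0.013439490445859872
uneven,1,10,1000,0.010769230769230769,0.4599406528189911,0.010415430267062315
uneven,2,1,200,0.009166666666666667,0.0,0.009166666666666667
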