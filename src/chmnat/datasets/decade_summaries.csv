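metric,decade_lower,n,age_mean,age_sd,age_median,value_mean,value_sd,value_median
va,1,10,8.3,1.2,9,0.075,0.118,0.05
va,11,28,16.0,2.7,17,0.045,0.126,0
va,21,17,25.5,2.8,26,0.016,0.059,0
va,31,19,36.0,2.9,37,0.099,0.172,0
va,41,24,46.0,2.7,46,0.372,0.497,0.3
va,51,15,54.6,2.3,55,0.818,0.765,0.5
va,61,12,65.2,3.1,64,0.848,0.845,0.439
va,71,3,72.7,1.2,72,2.567,0.231,2.7
vf,1,5,8.8,0.5,9,73,51,60
vf,11,16,15.6,2.6,15.5,74,56,50
vf,21,7,25.9,2.5,26,42,45,25
vf,31,7,35.3,3.1,37,19,11,15
vf,41,15,45.9,2.6,46,13,9,12
vf,51,10,54.3,2.9,54.5,6,6,5
vf,61,4,65.0,2.8,64,4,2,4
vf,71,0,,,,,,
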