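radius_mm,dose_weight
0.00,1.000000e+00
0.20,6.703200e-01
0.40,4.493290e-01
0.60,3.011942e-01
0.80,2.018965e-01
1.00,1.353353e-01
1.20,9.071795e-02
1.40,6.081006e-02
1.60,4.076220e-02
1.80,2.732372e-02
2.00,1.831564e-02
2.20,1.227734e-02
2.40,8.229747e-03
2.60,5.516564e-03
2.80,3.697864e-03
3.00,2.478752e-03
3.20,1.661557e-03
3.40,1.113775e-03
3.60,7.465858e-04
3.80,5.004514e-04
4.00,3.354626e-04
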