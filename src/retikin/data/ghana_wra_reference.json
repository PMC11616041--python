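{
 "L(2,1)": 30.0,
 "L(0,1)": 9.99,
 "L(3,2)": 30.0,
 "L(5,2)": 0.3,
 "L(4,3)": 1.0,
 "L(5,4)": 0.946414,
 "L(6,5)": 5.23994,
 "L(5,6)": 0.0184312,
 "L(7,5)": 4.73927,
 "L(5,7)": 0.302567,
 "L(0,6)": 0.00070779,
 "L(8,5)": 0.19378,
 "L(0,8)": 1.0,
 "DT(3)": 0.129438,
 "DT(8)": 0.052,
 "M(5)": 3.362,
 "dose_umol": 6.84
}
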