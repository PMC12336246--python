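sample,Ex_pa,Ey_pa,Gxy_pa,vxy
1,2230.0,2460.0,657.40,0.13
2,2670.0,2250.0,660.09,0.12
3,2820.0,4010.0,647.52,0.12
4,4350.0,3790.0,661.26,0.16
5,172.0,2140.0,649.78,0.13
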