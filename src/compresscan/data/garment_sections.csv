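sample,section,circumference_mm,height_mm
1,1,765,75
1,2,830,90
1,3,424,95
1,4,310,185
1,5,280,100
1,6,220,195
2,1,740,75
2,2,790,90
2,3,490,95
2,4,330,185
2,5,300,100
2,6,234,195
3,1,760,75
3,2,840,90
3,3,420,95
3,4,330,185
3,5,300,100
3,6,240,195
4,1,760,75
4,2,840,90
4,3,450,95
4,4,330,185
4,5,300,100
4,6,230,195
5,1,800,75
5,2,860,90
5,3,480,95
5,4,340,185
5,5,290,100
5,6,230,195
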