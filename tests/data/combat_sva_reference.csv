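"","s0","s1","s2","s3","s4","s5","s6","s7","s8","s9"
"p0",0.2848674058,1.1387071323,0.9697369962,1.7751061475,1.5500995511,1.5835094693,0.0875060132,-0.4404495312,1.6227886606,1.770601635
"p1",0.6901372241,-1.2919421078,1.4233855888,0.5009523227,0.4479464248,-0.1753010589,0.4293072765,-0.9927958587,0.9611520603,0.4949045281
"p2",0.0843387733,0.5974138828,1.7563475438,1.1953016034,-0.8179643311,1.6192324998,1.1604126641,0.6309415305,-0.0049282149,2.3293330037
"p3",1.4595149976,-0.0516520386,-0.2082192527,-1.048408225,0.0604511636,1.8881599655,-0.7947484438,2.7588735765,0.5321137574,0.5422107016
"p4",1.1621495116,0.2190463582,-0.6866329181,0.8755924829,0.7656449707,-1.2110103384,-1.5440814173,0.9686922747,-0.4742808856,0.7749483247
"p5",-0.7672280341,1.5438284893,0.128519724,0.0063522535,2.1863698961,0.5048725159,1.1150634849,0.4639581566,-0.3289882106,-0.5542080426
"p6",1.8371493545,0.8272210177,1.4850441513,0.9377240411,0.0341036107,-0.4243248791,1.4021922291,-0.2183802761,0.6087468661,1.5124577629
"p7",1.9927963884,1.8489458472,-0.2066000926,0.2339454549,0.0659088224,-0.615764127,1.4048889739,0.6642669829,1.6529777066,0.6346501829
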