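name,dim,lower_bound,upper_bound,printed_optimum,category,stochastic
F1,30,-100.0,100.0,0.0,unimodal,False
F2,30,-10.0,10.0,0.0,unimodal,False
F3,30,-100.0,100.0,0.0,unimodal,False
F4,30,-100.0,100.0,0.0,unimodal,False
F5,30,-30.0,30.0,0.0,unimodal,False
F6,30,-100.0,100.0,0.0,unimodal,False
F7,30,-1.28,1.28,0.0,unimodal,True
F8,30,-500.0,500.0,-12569.487,multimodal,False
F9,30,-5.12,5.12,0.0,multimodal,False
F10,30,-32.0,32.0,0.0,multimodal,False
F11,30,-600.0,600.0,0.0,multimodal,False
F12,30,-50.0,50.0,0.0,multimodal,False
F13,30,-50.0,50.0,0.0,multimodal,False
F14,2,-65.0,65.0,1.0,fixed_dimension_multimodal,False
F15,4,-5.0,5.0,0.0003,fixed_dimension_multimodal,False
F16,2,-5.0,5.0,-1.0316,fixed_dimension_multimodal,False
F17,2,-5.0,5.0,0.398,fixed_dimension_multimodal,False
F18,2,-2.0,2.0,3.0,fixed_dimension_multimodal,False
F19,3,0.0,1.0,-3.86,fixed_dimension_multimodal,False
F20,6,0.0,1.0,-3.32,fixed_dimension_multimodal,False
F21,4,0.0,10.0,-10.1532,fixed_dimension_multimodal,False
F22,4,0.0,10.0,-10.4028,fixed_dimension_multimodal,False
F23,4,0.0,10.0,-10.5363,fixed_dimension_multimodal,False
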