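sample_id,age_cal_bp,age_is_bound,region,material
L267,49000,true,Chukotka,Tusk
L272,47400,true,Chukotka,Tusk
L155,47772,false,Chukotka,Tooth
L156,49466,false,Chukotka,Femur
M2,38000,true,Wrangel (pre-isolation),Tooth
L163,30525,false,Chukotka,Tusk
L152,23891,false,Chukotka,Tooth
M6,24063,false,Wrangel (pre-isolation),Tooth
M7,21846,false,Wrangel (pre-isolation),Bone
L164,16901,false,Chukotka,Tusk
L158,14431,false,Chukotka,Humerus
M9,13872,false,Wrangel (pre-isolation),Tooth
M17,8318,false,Wrangel Island,Tooth
M23,7470,false,Wrangel Island,Tusk
M28,6380,false,Wrangel Island,Tusk
L385,6074,false,Wrangel Island,Tooth
L387,5601,false,Wrangel Island,Tooth
M32,5131,false,Wrangel Island,Tooth
E460,4969,false,Wrangel Island,Tusk
E461,4959,false,Wrangel Island,Bone
M38,4726,false,Wrangel Island,Tooth
E466,4354,false,Wrangel Island,Tusk
M42,4336,false,Wrangel Island,Tooth
E468,4079,false,Wrangel Island,Tusk
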