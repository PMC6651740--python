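code,group,pre_rhr,pre_hrr,post_rhr,post_hrr
E2,reference,76,32,68,45
E3,reference,75,30,67,42
E4,reference,76,32,68,44
E6,reference,71,42,60,50
E11,reference,60,46,56,51
E12,reference,58,52,55,52
E13,reference,80,33,66,42
E16,reference,70,38,67,40
E17,reference,74,38,65,43
E20,reference,70,42,65,48
E24,reference,76,32,66,43
E25,reference,79,31,69,42
E1,control,82,21,71,40
E5,control,76,22,71,39
E7,control,80,21,67,45
E8,control,75,25,71,38
E9,control,78,20,71,33
E10,control,82,18,70,37
E14,control,78,18,72,34
E15,control,75,22,71,36
E18,control,68,48,58,56
E19,control,79,25,70,41
E21,control,81,20,68,40
E22,control,79,21,69,42
E23,control,81,20,70,41
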