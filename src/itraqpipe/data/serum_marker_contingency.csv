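variable,level,low_hsp27,high_hsp27
status,Normal,18,0
status,ccRCC,25,11
sex,Male,15,8
sex,Female,10,3
grade,Low (1-2),15,11
grade,High (3-4),10,0
stage,Low (1-2),15,9
stage,High (3),10,2
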