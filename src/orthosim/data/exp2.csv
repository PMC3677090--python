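experiment,response,target_class,condition,prime_example,target_example,rt_ms,pct_error,sig_flag
exp2,Same,7letter,0L,bo,ABOLISH,463,4.2,1
exp2,Same,7letter,1L,bl,ABOLISH,463,4.5,1
exp2,Same,7letter,3L,bs,ABOLISH,459,5.5,1
exp2,Same,7letter,ALD,du,ABOLISH,487,4.2,0
exp2,Different,7letter,0L,bo,ABOLISH,513,3.0,0
exp2,Different,7letter,1L,bl,ABOLISH,508,3.9,0
exp2,Different,7letter,3L,bs,ABOLISH,515,3.6,0
exp2,Different,7letter,ALD,du,ABOLISH,516,3.9,0
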