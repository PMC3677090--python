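experiment,response,target_class,condition,prime_example,target_example,rt_ms,pct_error,sig_flag
exp3,Same,7letter,0L,bo,ABOLISH,455,3.7,1
exp3,Same,7letter,3L,bs,ABOLISH,459,3.2,1
exp3,Same,7letter,rev0L,ob,ABOLISH,466,4.3,1
exp3,Same,7letter,rev3L,sb,ABOLISH,471,4.2,1
exp3,Same,7letter,ALD,du,ABOLISH,484,6.3,0
exp3,Different,7letter,0L,bo,ABOLISH,498,2.5,0
exp3,Different,7letter,3L,bs,ABOLISH,509,2.2,0
exp3,Different,7letter,rev0L,ob,ABOLISH,500,1.8,0
exp3,Different,7letter,rev3L,sb,ABOLISH,501,1.8,0
exp3,Different,7letter,ALD,du,ABOLISH,500,2.2,0
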