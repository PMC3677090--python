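experiment,response,target_class,condition,prime_example,target_example,rt_ms,pct_error,sig_flag
exp1,Same,2letter,identity,of,OF,380,2.1,1
exp1,Same,2letter,TL,fo,OF,420,7.5,1
exp1,Same,2letter,ALD,ym,OF,477,9.2,0
exp1,Same,3letter,identity,the,THE,389,4.2,1
exp1,Same,3letter,TL,hte,THE,423,3.8,1
exp1,Same,3letter,ALD,nma,THE,471,12.1,0
exp1,Different,2letter,identity,of,OF,476,4.2,0
exp1,Different,2letter,TL,fo,OF,471,5.0,0
exp1,Different,2letter,ALD,ym,OF,473,5.4,0
exp1,Different,3letter,identity,the,THE,472,5.8,0
exp1,Different,3letter,TL,hte,THE,475,2.9,0
exp1,Different,3letter,ALD,mna,THE,501,3.3,0
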