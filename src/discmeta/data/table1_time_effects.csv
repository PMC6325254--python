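study_id,group,tracer_target,region,index,r,t,df,n,exclude,note
joutsa,addiction,d2_receptor,ventral striatum,k,-0.700,,,12,0,pathological gambling; raclopride baseline BPND
joutsa,healthy,d2_receptor,ventral striatum,k,-0.010,,,12,0,control; raclopride baseline BPND
joutsa,addiction,d2_receptor,ventral striatum,k,-0.890,,,12,0,pathological gambling; raclopride DA release
joutsa,healthy,d2_receptor,ventral striatum,k,0.150,,,12,0,control; raclopride DA release
joutsa,other_psychopathology,da_synthesis,caudate,k,0.640,,,17,0,Parkinson's disease; FDOPA synthesis capacity
ballard,addiction,d2_receptor,whole striatum,ln_k,-0.342,,,27,0,methamphetamine users; fallypride
ballard,healthy,d2_receptor,whole striatum,ln_k,-0.179,,,27,0,control; fallypride
oberlin,addiction,d2_receptor,ventral striatum,auc,0.650,,,10,0,non-treatment-seeking alcoholism; raclopride
oberlin,healthy,d2_receptor,ventral striatum,auc,0.611,,,11,0,social drinkers; raclopride
eisenstein,other_psychopathology,d2_receptor,whole striatum,auc,-0.560,,,23,0,obesity; NMB; partial r
eisenstein,healthy,d2_receptor,whole striatum,auc,0.050,,,19,0,control; NMB; partial r
fmt_synthesis,healthy,da_synthesis,putamen,proportion_smaller,-0.513,,,16,0,FMT synthesis capacity; Spearman rho used as r
fpcit_dat,other_psychopathology,dat,putamen,occupancy_correlate,-0.536,,,24,0,ADHD; FP-CIT SPECT; r vs methylphenidate occupancy (inverse of DAT availability)
present,healthy,d2_receptor,whole striatum,proportion_smaller,0.027,,,109,0,fallypride; partial r controlling age sex and sample
phno_quadratic,healthy,d2_receptor,pallidum,ln_k,,,,11,1,quadratic-only report; no linear correlation available
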