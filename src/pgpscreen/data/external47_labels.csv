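compound_id,inhibition,atpase,efflux,strong_inhibitor
I_8b,Y,N,Y,false
II_11a,Y,N,N,false
II_11b,Y,N,Y,false
II_13a,Y,N,Y,false
II_13b,Y,N,Y,false
II_14a,Y,N,N,true
II_14b,Y,Y,Y,true
II_15a,Y,N,N,true
II_15b,Y,N,Y,true
II_16a,Y,N,Y,true
II_16b,Y,N,Y,false
II_17b,Y,Y,N,true
II_23,Y,N,Y,true
II_25,Y,N,Y,true
II_26,Y,N,Y,true
II_27,Y,N,Y,true
III_5a,Y,N,Y,false
III_5b,Y,N,Y,false
III_5c,Y,N,Y,true
III_5d,Y,N,Y,false
III_6b,Y,N,Y,false
III_6c,Y,N,Y,true
III_7a,N,Y,Y,false
III_7b,Y,Y,Y,false
III_7c,Y,Y,Y,false
III_7d,Y,Y,Y,true
III_8a,Y,Y,Y,false
III_8b,Y,Y,Y,false
III_8c,Y,Y,Y,true
III_8d,Y,Y,Y,false
III_9a,Y,N,Y,true
III_9b,Y,N,Y,true
III_9c,Y,N,Y,true
III_9d,Y,N,Y,true
III_10a,Y,N,Y,true
III_10b,Y,N,Y,false
III_10c,Y,N,Y,true
III_10d,Y,N,Y,false
III_11a,Y,N,Y,false
III_11b,Y,N,Y,true
III_11c,Y,N,Y,true
III_11d,Y,N,Y,false
III_12a,Y,Y,Y,true
III_12b,Y,N,Y,true
III_12c,Y,N,Y,true
III_12d,Y,Y,Y,true
MV181,N,N,Y,false
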