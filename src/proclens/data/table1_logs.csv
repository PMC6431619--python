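person_id,time,etype,top,central,bottom
student1,0,start,,,
student1,29.5,apply,2,0,0
student1,32.4,apply,0,0,0
student1,35.2,reset,,,
student1,36.2,apply,0,0,0
student1,61.5,end,,,
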