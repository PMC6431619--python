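person_id,duration,outcome
student1,61.5,1
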