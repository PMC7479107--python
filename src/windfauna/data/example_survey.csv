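name,presence_count,individual_count
Falco naumanni,30,20
Gyps fulvus,50,30
Turdus merula,20,50
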