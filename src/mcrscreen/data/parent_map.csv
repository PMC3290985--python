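metabolite,parent
Aldicarb sulfone,Aldicarb
Aldicarb sulfoxide,Aldicarb
2-Chloro-4-isopropylamino-6-amino-s-triazine,Atrazine
Deethylatrazine,Atrazine
Deisopropylatrazine,Atrazine
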