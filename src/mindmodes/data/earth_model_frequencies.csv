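model,grade1,grade3,grade5,total
Flat earth,1,0,0,1
Disk earth,0,1,0,1
Dual earth,6,2,0,8
Hollow sphere,2,4,6,12
Flattened sphere,1,3,0,4
Sphere,3,8,12,23
Mixed,7,2,2,11
Total,20,20,20,60
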