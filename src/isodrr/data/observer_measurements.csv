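measurement,modality,obs1,obs2,obs3,obs4
ANS-Petrous,real,47,48,51,47
ANS-Petrous,drr,47,50,47,45
Petrous-Bregma,real,119,116,110,119
Petrous-Bregma,drr,117,118,114,116
Lt TMJ-Sella,real,26,25,28,27
Lt TMJ-Sella,drr,27,28,28,26
Sella-Rt Mastoid,real,66,66,65,68
Sella-Rt Mastoid,drr,62,64,67,65
Lt Outer Canthus-Sella,real,38,37,37,37
Lt Outer Canthus-Sella,drr,39,34,34,33
Sella-Lt EAM,real,32,38,33,35
Sella-Lt EAM,drr,32,33,32,33
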