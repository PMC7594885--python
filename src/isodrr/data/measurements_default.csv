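measurement,projection,landmark_a,landmark_b,plane
ANS-Petrous,OF15,ANS,Petrous,sagittal
Petrous-Bregma,OF15,Petrous,Bregma,sagittal
Lt TMJ-Sella,Lat,Lt TMJ,Sella,coronal
Sella-Rt Mastoid,Lat,Sella,Rt Mastoid,coronal
Lt Outer Canthus-Sella,Lat,Lt Outer Canthus,Sella,axial
Sella-Lt EAM,Lat,Sella,Lt EAM,axial
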