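measurement,plane,real_mean,real_sd,drr_mean,drr_sd,diff_of_means
ANS-Petrous,sagittal,48.3,1.9,47.3,2.1,1.0
Petrous-Bregma,sagittal,114.8,3.8,116.3,1.7,-1.5
Lt TMJ-Sella,coronal,26.8,1.5,27.3,1.0,-0.5
Sella-Rt Mastoid,coronal,66.0,0.8,64.5,2.1,1.5
Lt Outer Canthus-Sella,axial,36.5,1.7,35.0,2.7,1.5
Sella-Lt EAM,axial,33.8,2.9,32.5,0.6,1.3
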