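# The three-projection study set: left lateral, occipito-frontal 15 degrees
# ("Pineal"), and fronto-occipital "Optic Foramina".  Angles are Dulac L/M
# degrees; displacements in mm (negative long = cranial isocentre shift).

[Lat]
L_deg = 90.0
M_deg = 90.0
raise_mm = 0.0
long_mm = -40.0

[OF15]
L_deg = 345.0
M_deg = 0.0
raise_mm = 0.0
long_mm = -40.0

[FO]
L_deg = 145.0
M_deg = 125.0
raise_mm = 0.0
long_mm = -40.0
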