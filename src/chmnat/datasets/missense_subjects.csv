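subject_id,family_id,hgvs_c,hgvs_c_2,protein_change,protein_change_2,age,onset_nyctalopia,onset_other,va_od,va_os,vf_od,vf_os,vf_isopter,vf_instrument
S1.1,F1,c.1649T>C,,p.L550P,,44,10,20,0.9,2.3,5,5,III4e,Goldmann
S1.2,F1,c.1649T>C,,p.L550P,,45,10,NC,0.7,0.5,NC,NC,III4e,Goldmann
S2.1,F2,c.819G>T,,p.Q273H,,51,5,43,1,0.8,20,10,III4e,Goldmann
S2.2,F2,c.819G>T,,p.Q273H,,22,NC,NC,0,0.18,135,31,III4e,Goldmann
S3.1,F3,c.1370T>C,,p.L457P,,9,7,7,0,0,130,130,III4e,Goldmann
S3.2,F3,c.1370T>C,,p.L457P,,17,15,15,0,0.1,140,120,III4e,Goldmann
S3.3,F3,c.1370T>C,,p.L457P,,70,30,30,3,2.3,NC,NC,III4e,Goldmann
S4.1,F4,c.238C>T,c.1327A>G,p.L80F,p.M443V,9,9,9,0,0,60,60,III4e,Goldmann
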