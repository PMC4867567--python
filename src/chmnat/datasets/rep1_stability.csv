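mutant,ddg_kcal_mol,u_printed,f_printed
p.Leu80Phe,0.467,0.685,0.315
p.Gln273His,1.482,0.922,0.078
p.Met443Val,6.423,1.000,0.000
p.Leu457Pro,8.475,1.000,0.000
p.Leu550Pro,7.539,1.000,0.000
p.Leu80Phe and p.Met443Val,5.795,1.000,0.000
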