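# Example Abraham LFER configuration table (editable).
# Phase rows carry effective temperature-averaged system coefficients c,e,s,a,b,l
# for a poly(dimethylsiloxane) first-dimension column (DB-1) and a 50%-phenyl
# second-dimension column (HP-50), anchored to published GC system-constant
# compilations. Solute rows carry Abraham descriptors E,S,A,B,L; provenance
# marks whether descriptors are experimental or estimated.
name,kind,E,S,A,B,L,provenance,c,e,s,a,b,l
DB-1,phase,,,,,,,-0.194,0.015,0.210,0.100,0.000,0.500
HP-50,phase,,,,,,,-0.370,0.071,0.653,0.263,0.000,0.418
"Phenol, 4-chloro-",solute,0.915,1.080,0.670,0.200,4.775,experimental,,,,,,
"Benzenamine, 2,4-dichloro-",solute,1.160,1.130,0.350,0.320,5.307,estimated,,,,,,
"Acetaldehyde, tribromo-",solute,0.693,0.950,0.000,0.320,4.750,estimated,,,,,,
"Phenol, 2,4,6-tribromo-",solute,1.520,1.200,0.580,0.160,7.030,estimated,,,,,,
"Benzonitrile, 2,6-dichloro-",solute,0.980,1.350,0.000,0.280,5.550,estimated,,,,,,
"Hexane, 2-bromo-",solute,0.350,0.480,0.000,0.120,4.200,estimated,,,,,,
naphthalene,solute,1.340,0.920,0.000,0.200,5.161,experimental,,,,,,
toluene,solute,0.601,0.520,0.000,0.140,3.325,experimental,,,,,,
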