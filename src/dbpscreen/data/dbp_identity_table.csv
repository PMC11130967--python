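id,name,cas,formula,molecular_ion,cosine_similarity,theoretical_mass_da,measured_mass_da,mass_error_ppm,dI
1,"Benzenamine, 2,4-dichloro-",554-00-7,C6H5Cl2N,appeared,0.998,160.9799,160.9691,67.1,7
2,"Benzonitrile, 2,6-dichloro-",1194-65-6,C7H3Cl2N,appeared,0.998,170.9643,170.9521,71.4,9
3,"Benzenamine, 2,3,4-trichloro-",634-67-3,C6H4Cl3N,appeared,0.997,194.9409,194.9260,76.6,
4,"Acetaldehyde, tribromo-",115-17-3,C2HBr3O,absent,,277.7578,,,
5,2-Bromo-4-chloroaniline,873-38-1,C6H5BrClN,appeared,0.995,204.9294,204.9137,76.7,7
6,Bromodichloroacetaldehyde,34619-29-9,C2HBrCl2O,absent,,189.8588,,,
7,"Benzaldehyde, 2,4-dichloro-",874-42-0,C7H4Cl2O,appeared,0.75,173.9639,173.9500,79.9,
8,"1H-Pyrazole, 3,4-dibromo-",5932-18-3,C3H2Br2N2,appeared,0.999,223.8585,223.8421,73.3,
9,"Acetic acid, dibromo-, methyl ester",6482-26-4,C3H4Br2O2,appeared,1,229.8578,229.8424,66.9,-19
10,"4-Bromo-2,6-dichloroaniline",697-86-9,C6H4BrCl2N,appeared,0.998,238.8904,238.8728,73.9,
11,"Benzene, 1,1'-(bromomethylene)bis-",776-74-9,C13H11Br,absent,,246.0044,,,25
12,Chlorodibromoacetaldehyde,64316-11-6,C2HBr2ClO,absent,,233.8083,,,
13,"Hexane, 2-bromo-",3377-86-4,C6H13Br,faint,,164.0201,,,-122
14,"Phenol, 4-chloro-",106-48-9,C6H5ClO,appeared,0.999,128.0029,127.9937,72.2,-30
15,"Phenol, 2,4,6-tribromo-",118-79-6,C6H3Br3O,appeared,1,327.7734,327.7469,80.8,67
16,"2-Propanone, 1,1,3-trichloro-",921-03-9,C3H3Cl3O,faint,0.995,159.9249,159.9128,75.8,2
17,"Acridine, 4,5-dibromo-",209460-03-7,C13H7Br2N,appeared,0.999,334.8945,334.8681,78.8,
18,"1,1,3,3-Tetrabromoacetone",22612-89-1,C3H2Br4O,faint,0.402,369.6839,369.6469,100.2,
19,"Tribromoacetic acid, methyl ester",3222-05-7,C3H3Br3O2,faint,0.519,307.7683,307.7469,69.6,14
20,"2,4,6-Trichlorophenyl isocyanate",2505-31-9,C7H2Cl3NO,appeared,0.998,220.9202,220.9028,78.6,
21,"2,6-Dibromo-4-chloroaniline",874-17-9,C6H4Br2ClN,appeared,1,282.8399,282.8178,78.2,
22,"Benzenamine, 2,4,5-trichloro-",636-30-6,C6H4Cl3N,appeared,0.994,194.9409,194.9271,70.7,-34
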