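id,sample_id,rt1_min,rt2_s,name,cas,mf,rmf,layer,flags
1,post,19.73,2.12,"Benzenamine, 2,4-dichloro-",554-00-7,933,941,1,
2,post,18.65,2.17,"Benzonitrile, 2,6-dichloro-",1194-65-6,921,928,1,
3,post,25.26,2.73,"Benzenamine, 2,3,4-trichloro-",634-67-3,905,909,1,
4,post,11.93,1.5,"Acetaldehyde, tribromo-",115-17-3,893,898,1,
5,post,21.9,2.37,2-Bromo-4-chloroaniline,873-38-1,893,911,1,
6,post,13.45,0.41,Bromodichloroacetaldehyde,34619-29-9,888,900,1,layer_only
7,post,17.89,1.75,"Benzaldehyde, 2,4-dichloro-",874-42-0,872,926,1,
8,post,22.55,2.58,"1H-Pyrazole, 3,4-dibromo-",5932-18-3,869,908,1,
9,post,11.72,1.34,"Acetic acid, dibromo-, methyl ester",6482-26-4,869,904,1,layer_only
10,post,23.85,2.17,"4-Bromo-2,6-dichloroaniline",697-86-9,859,901,1,
11,post,26.67,3.35,"Benzene, 1,1'-(bromomethylene)bis-",776-74-9,854,932,1,layer_only
12,post,10.2,0.98,Chlorodibromoacetaldehyde,64316-11-6,851,909,1,
13,post,10.31,0.52,"Hexane, 2-bromo-",3377-86-4,841,883,2,
14,post,16.48,1.65,"Phenol, 4-chloro-",106-48-9,836,905,1,
15,post,26.88,2.53,"Phenol, 2,4,6-tribromo-",118-79-6,834,930,2,layer_only
16,post,10.85,1.19,"2-Propanone, 1,1,3-trichloro-",921-03-9,832,864,1,layer_only
17,post,40.75,3.92,"Acridine, 4,5-dibromo-",209460-03-7,830,872,1,
18,post,21.36,2.73,"1,1,3,3-Tetrabromoacetone",22612-89-1,821,862,1,
19,post,16.37,1.96,"Tribromoacetic acid, methyl ester",3222-05-7,821,898,1,
20,post,22.33,1.5,"2,4,6-Trichlorophenyl isocyanate",2505-31-9,818,911,2,layer_only
21,post,26.12,2.48,"2,6-Dibromo-4-chloroaniline",874-17-9,810,864,1,
22,post,21.68,1.86,"Benzenamine, 2,4,5-trichloro-",636-30-6,810,854,1,layer_only
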