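strain_id,species_name,phylum,D10_kGy,CIRgrowth,lowpHgrowth,Tmax_C,HgCl2_uM,MER_uM,CrCl3_uM,K2Cr2O7_uM,uncertain_fields
EXF-7729,Cryptococcus laurentii,B,6.5,1,1,30.0,10.0,750.0,500.0,25.0,
EXF-3792,Cryptococcus fonsecae,B,4.2,1,1,39.0,25.0,1000.0,500.0,50.0,
EXF-6424,Trichosporon moniliiforme,B,4.1,1,1,39.0,25.0,500.0,750.0,1000.0,
EXF-6430,Ustilago davisii,B,4.0,1,1,37.0,25.0,2000.0,3500.0,100.0,
EXF-5822,Saccharomyces cerevisiae,A,3.6,1,1,40.0,25.0,500.0,500.0,100.0,
EXF-6246,Saccharomyces cerevisiae,A,3.5,0,1,40.0,25.0,100.0,500.0,100.0,
EXF-5294,Saccharomyces cerevisiae,A,3.2,0,1,40.0,25.0,250.0,500.0,10.0,
EXF-5576,Exophiala dermatitidis A,A,3.0,1,1,45.0,25.0,100.0,1000.0,500.0,
EXF-5586,Exophiala dermatitidis B,A,3.0,1,1,45.0,50.0,100.0,1000.0,250.0,
EXF-5585,Exophiala dermatitidis C,A,3.0,1,1,50.0,50.0,100.0,750.0,750.0,
EXF-6408,Metschnikowia fructicola,A,3.0,1,1,39.0,10.0,1000.0,500.0,100.0,
EXF-4909,Saccharomyces bayanus x cerivisiae,A,3.0,1,1,40.0,25.0,750.0,500.0,500.0,
EXF-5282,Saccharomyces cerevisiae,A,3.0,1,1,40.0,10.0,50.0,100.0,10.0,
EXF-5284,Saccharomyces cerevisiae,A,3.0,1,1,40.0,25.0,2500.0,1000.0,500.0,
EXF-6248,Saccharomyces cerevisiae,A,3.0,0,1,37.0,25.0,15.0,500.0,10.0,
EXF-6761,Saccharomyces cerevisiae,A,3.0,1,1,40.0,25.0,100.0,500.0,500.0,
EXF-5295,Saccharomyces cerevisiae,A,2.8,1,1,40.0,25.0,500.0,500.0,500.0,
EXF-7173,Saccharomyces paradoxus,A,2.8,0,1,40.0,10.0,50.0,100.0,250.0,
EXF-4916,Saccharomyces cerevisiae,A,2.6,1,1,40.0,25.0,1000.0,500.0,1000.0,
EXF-5281,Saccharomyces cerevisiae,A,2.6,1,1,40.0,10.0,50.0,100.0,250.0,
EXF-5046,Saccharomyces cerevisiae,A,2.5,1,1,40.0,25.0,3000.0,500.0,1000.0,
EXF-7200,Saccharomyces cerevisiae,A,2.5,1,1,40.0,25.0,500.0,500.0,100.0,
EXF-7135,Saccharomyces paradoxus,A,2.5,1,1,40.0,25.0,50.0,100.0,250.0,
EXF-8528,Rhodotorula nothofagi,B,2.5,0,0,25.0,25.0,100.0,500.0,10.0,
MD-1149,Rhodotorula taiwanensis,B,2.5,1,1,32.0,50.0,500.0,500.0,100.0,
EXF-6676,Saccharomyces paradoxus,A,2.4,0,1,40.0,25.0,50.0,100.0,100.0,
EXF-8581,Rhodotorula fujisanensis,B,2.1,0,0,25.0,10.0,100.0,100.0,25.0,
EXF-5283,Metschnikowia pulcherrima,A,2.0,1,1,39.0,10.0,1000.0,750.0,1000.0,
EXF-6398,Pichia kudravzevii,A,2.0,1,1,45.0,25.0,100.0,500.0,750.0,
EXF-5293,Saccharomyces bayanus,A,2.0,1,1,40.0,25.0,3000.0,500.0,100.0,
EXF-3422,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,2500.0,500.0,500.0,
EXF-4911,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,1000.0,500.0,1000.0,
EXF-5042,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,3000.0,500.0,500.0,
EXF-5248,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,3000.0,500.0,500.0,
EXF-5735,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,1000.0,500.0,500.0,
EXF-5872,Saccharomyces cerevisiae,A,2.0,0,1,40.0,25.0,750.0,500.0,100.0,
EXF-6247,Saccharomyces cerevisiae,A,2.0,0,1,40.0,25.0,500.0,100.0,500.0,
EXF-6684,Saccharomyces cerevisiae,A,2.0,1,1,40.0,25.0,100.0,500.0,500.0,
EXF-7284,Saccharomyces kudriavzevii,A,2.0,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-308,Rhodotorula rubra,B,2.0,1,1,37.0,25.0,1000.0,750.0,100.0,
EXF-6464,Debaryomyces hansenii,A,1.8,1,1,39.0,10.0,100.0,500.0,250.0,
EXF-5297,Saccharomyces cerevisiae,A,1.8,1,1,40.0,25.0,1000.0,100.0,500.0,
EXF-5875,Saccharomyces cerevisiae,A,1.8,0,1,40.0,25.0,1000.0,100.0,500.0,
EXF-7197,Saccharomyces cerevisiae,A,1.8,1,1,40.0,25.0,500.0,500.0,100.0,
EXF-7137,Saccharomyces paradoxus,A,1.8,0,1,40.0,10.0,50.0,100.0,250.0,
EXF-5043,Saccharomyces cerevisiae,A,1.6,1,1,40.0,25.0,300.0,100.0,250.0,
EXF-6789,Saccharomyces cerevisiae,A,1.6,1,1,40.0,25.0,500.0,500.0,100.0,
EXF-1630,Rhodotorula mucilaginosa,B,1.6,1,1,37.0,25.0,1000.0,750.0,100.0,
EXF-7207,Saccharomyces kudriavzevii,A,1.5,0,1,39.0,10.0,50.0,100.0,100.0,
EXF-7211,Saccharomyces kudriavzevii,A,1.5,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-7288,Saccharomyces kudriavzevii,A,1.5,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-1612,Rhodosporidium lusitaniae,B,1.5,0,1,25.0,10.0,100.0,500.0,100.0,
EXF-6410,Pichia fermentans,A,1.4,1,1,39.0,10.0,1000.0,500.0,500.0,
EXF-3501,Rhodosporidium diobovatum,B,1.4,1,1,37.0,25.0,1000.0,750.0,100.0,
EXF-6402,Kazachstania exigua,A,1.2,1,1,39.0,10.0,100.0,750.0,50.0,
EXF-6835,Saccharomyces cerevisiae,A,1.2,0,1,40.0,7.5,50.0,100.0,750.0,
EXF-7202,Saccharomyces cerevisiae,A,1.2,1,1,40.0,25.0,100.0,500.0,100.0,
EXF-3697,Rhodosporidium kratochvilovae,B,1.2,1,1,37.0,50.0,1000.0,500.0,250.0,
EXF-8527,Rhodotorula colostri,B,1.2,0,0,25.0,25.0,250.0,250.0,100.0,
EXF-6435,Rhodotorula glutinis,B,1.2,1,1,30.0,25.0,1000.0,500.0,100.0,
EXF-5870,Saccharomyces cerevisiae,A,1.1,0,1,40.0,25.0,500.0,500.0,100.0,
EXF-512,Rhodosporidium sphaerocarpum,B,1.1,1,1,30.0,25.0,1000.0,500.0,500.0,
EXF-5557,Rhodotorula slooffiae,B,1.1,1,1,37.0,25.0,100.0,500.0,250.0,
EXF-1534,Rhodotorula lysinophila,B,1.1,1,1,37.0,25.0,1000.0,500.0,250.0,
EXF-1529,Rhodotorula minuta,B,1.1,1,1,37.0,25.0,1000.0,500.0,250.0,
EXF-7977,Candida sake,A,1.0,1,1,39.0,10.0,1000.0,750.0,1000.0,
EXF-6453,Cyberlindnera saturnus,A,1.0,1,1,39.0,25.0,500.0,2000.0,3500.0,
EXF-1496,Pichia guilliermondi,A,1.0,1,1,43.0,25.0,250.0,750.0,1500.0,
EXF-5733,Saccharomyces cerevisiae,A,1.0,0,1,40.0,10.0,3000.0,500.0,100.0,
EXF-6780,Saccharomyces cerevisiae,A,1.0,1,1,40.0,25.0,300.0,100.0,250.0,
EXF-7163,Saccharomyces kudriavzevii,A,1.0,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-7210,Saccharomyces kudriavzevii,A,1.0,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-7282,Saccharomyces kudriavzevii,A,1.0,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-7289,Saccharomyces kudriavzevii,A,1.0,0,1,39.0,10.0,50.0,100.0,250.0,
EXF-6421,Schwanniomyces pseudopolymorphus,A,1.0,0,0,39.0,10.0,1000.0,500.0,100.0,
EXF-3409,Cryptococcus liquefaciens,B,1.0,1,1,39.0,25.0,1000.0,750.0,50.0,
EXF-513,Rhodosporidium babjevae,B,1.0,0,1,30.0,25.0,1000.0,500.0,50.0,
EXF-3661,Rhodosporidium lusitaniae,B,1.0,0,1,25.0,25.0,1500.0,250.0,25.0,
EXF-6094,Rhodotorula calyptogenae,B,1.0,1,1,40.0,25.0,1000.0,500.0,100.0,
EXF-9815,Rhodotorula aurantica,B,1.0,0,0,25.0,2.5,10.0,100.0,10.0,
EXF-6425,Rhodotorula glutinis,B,1.0,1,1,39.0,50.0,1000.0,500.0,100.0,
EXF-7964,Wickerhamomyces anomalus,A,0.9,1,1,40.0,10.0,1500.0,3500.0,1500.0,
EXF-3800,Rhodotorula benthica,B,0.9,0,1,25.0,10.0,1000.0,500.0,75.0,
EXF-3909,Rhodotorula laryngis,B,0.9,0,1,25.0,25.0,1000.0,750.0,25.0,
EXF-7107,Geotrichum sp,A,0.8,1,1,45.0,10.0,100.0,500.0,100.0,
EXF-5871,Saccharomyces cerevisiae,A,0.8,1,1,40.0,25.0,1000.0,500.0,100.0,
EXF-5288,Kluyveromyces marxianus,A,0.6,1,1,45.0,10.0,1000.0,500.0,100.0,
EXF-6218,Saccharomyces cerevisiae,A,0.6,0,1,40.0,25.0,500.0,500.0,1000.0,
EXF-6219,Saccharomyces cerevisiae,A,0.6,0,1,40.0,5.0,300.0,100.0,250.0,
EXF-6436,Occultifur externus,B,0.6,0,1,37.0,25.0,1000.0,500.0,250.0,
EXF-6463,Candida pseudoloambica,A,0.5,1,1,39.0,10.0,1500.0,3500.0,75.0,
EXF-7145,Saccharomyces cerevisiae,A,0.5,0,1,40.0,25.0,250.0,100.0,500.0,
EXF-7167,Saccharomyces paradoxus,A,0.5,1,1,40.0,25.0,50.0,100.0,250.0,
EXF-3801,Rhodosporidium fluviale,B,0.5,0,1,25.0,25.0,1000.0,500.0,50.0,
EXF-589,Debaryomyces hansenii,A,0.3,0,1,39.0,10.0,100.0,250.0,100.0,
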