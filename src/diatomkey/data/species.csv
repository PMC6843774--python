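species_id,binomial,genus,family,length_min_um,length_max_um,width_min_um,width_max_um,striae_min_10um,striae_max_10um,fibulae_min_10um,fibulae_max_10um,ecology_tag,synonyms,provenance
melosira_varians,Melosira varians,Melosira,Melosiraceae,8,35,8,35,,,,,mesotrophic,,flora_approx
rhoicosphenia_abbreviata,Rhoicosphenia abbreviata,Rhoicosphenia,Rhoicospheniaceae,12,75,3,8,9,16,,,unknown,,flora_approx
cyclotella_meneghiniana,Cyclotella meneghiniana,Cyclotella,Stephanodiscaceae,5,43,5,43,6,10,,,unknown,,flora_approx
cyclotella_ocellata,Cyclotella ocellata,Cyclotella,Stephanodiscaceae,5,25,5,25,13,19,,,unknown,,flora_approx
cyclotella_comta,Cyclotella comta,Cyclotella,Stephanodiscaceae,10,40,10,40,12,18,,,unknown,,flora_approx
bacillaria_paxillifera,Bacillaria paxillifera,Bacillaria,Bacillariaceae,50,150,4,8,20,25,6,10,unknown,,flora_approx
rhopalodia_gibba,Rhopalodia gibba,Rhopalodia,Rhopalodiaceae,30,300,8,13,11,18,5,8,unknown,,flora_approx
epithemia_sorex,Epithemia sorex,Epithemia,Rhopalodiaceae,8,65,8,15,11,18,5,8,unknown,,flora_approx
epithemia_adnata,Epithemia adnata,Epithemia,Rhopalodiaceae,15,150,7,14,11,14,2,5,unknown,,flora_approx
nitzschia_constricta,Nitzschia constricta,Nitzschia,Bacillariaceae,20,60,5,10,20,26,8,12,unknown,,flora_approx
nitzschia_hungarica,Nitzschia hungarica,Nitzschia,Bacillariaceae,20,100,5,10,16,20,7,10,eutrophic,,flora_approx
nitzschia_amphibia,Nitzschia amphibia,Nitzschia,Bacillariaceae,12,50,4,6,15,19,7,9,unknown,,flora_approx
nitzschia_linearis,Nitzschia linearis,Nitzschia,Bacillariaceae,50,120,5,7,28,32,8,13,unknown,,flora_approx
nitzschia_angusta,Nitzschia angusta,Nitzschia,Bacillariaceae,30,90,5,8,24,30,6,11,unknown,Nitzschia angustata,flora_approx
nitzschia_angustatula,Nitzschia angustatula,Nitzschia,Bacillariaceae,15,40,3,5,28,35,10,14,unknown,,flora_approx
nitzschia_clausii,Nitzschia clausii,Nitzschia,Bacillariaceae,25,80,3,5,30,38,8,12,unknown,,flora_approx
nitzschia_sigma,Nitzschia sigma,Nitzschia,Bacillariaceae,40,200,4,9,23,26,7,11,unknown,,flora_approx
nitzschia_inconspicua,Nitzschia inconspicua,Nitzschia,Bacillariaceae,4,15,2,4,28,32,9,14,unknown,,flora_approx
nitzschia_dissipata,Nitzschia dissipata,Nitzschia,Bacillariaceae,15,60,3,7,30,40,6,9,unknown,,flora_approx
nitzschia_fonticola,Nitzschia fonticola,Nitzschia,Bacillariaceae,10,40,3,5,23,28,8,13,unknown,,flora_approx
nitzschia_frustulum,Nitzschia frustulum,Nitzschia,Bacillariaceae,8,40,2,4.5,22,26,9,14,unknown,,flora_approx
nitzschia_capitellata,Nitzschia capitellata,Nitzschia,Bacillariaceae,15,60,3.5,5.5,30,40,8,13,unknown,,flora_approx
nitzschia_palea,Nitzschia palea,Nitzschia,Bacillariaceae,15,70,2.5,5,30,40,9,14,unknown,,flora_approx
fragilaria_capucina_var_capitellata,Fragilaria capucina var. capitellata,Fragilaria,Fragilariaceae,20,60,2,4,12,18,,,unknown,,flora_approx
fragilaria_capucina_var_capucina,Fragilaria capucina var. capucina,Fragilaria,Fragilariaceae,25,100,2,5,9,17,,,unknown,,flora_approx
fragilaria_vaucheriae,Fragilaria vaucheriae,Fragilaria,Fragilariaceae,10,50,3,5,9,14,,,unknown,,flora_approx
ulnaria_acus,Ulnaria acus,Ulnaria,Ulnariaceae,60,250,2,5,10,14,,,unknown,,flora_approx
ulnaria_ulna,Ulnaria ulna,Ulnaria,Ulnariaceae,50,350,3,9,8,12,,,unknown,,flora_approx
pseudostaurosira_brevistriata,Pseudostaurosira brevistriata,Pseudostaurosira,Staurosiraceae,5,25,2,5,13,17,,,unknown,,flora_approx
staurosira_construens_var_venter,Staurosira construens var. venter,Staurosira,Staurosiraceae,5,25,2,8,14,18,,,unknown,,flora_approx
planothidium_lanceolatum,Planothidium lanceolatum,Planothidium,Achnanthidiaceae,8,30,3,8,10,15,,,unknown,,flora_approx
achnanthidium_minutissimum,Achnanthidium minutissimum,Achnanthidium,Achnanthidiaceae,5,25,2,4,25,35,,,oligotrophic,,flora_approx
achnanthidium_eutrophilum,Achnanthidium eutrophilum,Achnanthidium,Achnanthidiaceae,5,15,2.5,4.5,25,32,,,unknown,,flora_approx
achnanthidium_biasolettianum,Achnanthidium biasolettianum,Achnanthidium,Achnanthidiaceae,6,20,2.5,5,22,30,,,unknown,,flora_approx
cocconeis_placentula,Cocconeis placentula,Cocconeis,Cocconeidaceae,8,40,5,25,19,26,,,unknown,,flora_approx
cocconeis_pediculus,Cocconeis pediculus,Cocconeis,Cocconeidaceae,10,35,7,25,15,20,,,unknown,,flora_approx
diatoma_mesodon,Diatoma mesodon,Diatoma,Tabellariaceae,8,40,5,12,18,26,,,oligotrophic,,flora_approx
diatoma_vulgaris,Diatoma vulgaris,Diatoma,Tabellariaceae,30,75,7,13,16,22,,,unknown,,flora_approx
meridion_circulare,Meridion circulare,Meridion,Tabellariaceae,10,80,4,8,14,18,,,unknown,,flora_approx
meridion_circulare_var_constricta,Meridion circulare var. constricta,Meridion,Tabellariaceae,12,60,4,8,14,18,,,unknown,,flora_approx
eolimna_subminuscula,Eolimna subminuscula,Eolimna,Naviculaceae,6,15,3,5,16,22,,,unknown,,flora_approx
eolimna_minima,Eolimna minima,Eolimna,Naviculaceae,5,20,2.5,4.5,20,26,,,eutrophic,,flora_approx
sellaphora_seminulum,Sellaphora seminulum,Sellaphora,Sellaphoraceae,5,20,2.5,5,16,22,,,unknown,,flora_approx
navicula_capitatoradiata,Navicula capitatoradiata,Navicula,Naviculaceae,20,45,7,10,12,16,,,mesotrophic,,flora_approx
navicula_cryptotenella,Navicula cryptotenella,Navicula,Naviculaceae,12,40,4,7,14,18,,,unknown,,flora_approx
gomphonema_parvulum,Gomphonema parvulum,Gomphonema,Gomphonemataceae,10,36,4,8,9,18,,,unknown,,flora_approx
gomphonema_pumilum,Gomphonema pumilum,Gomphonema,Gomphonemataceae,10,30,3,6,10,14,,,unknown,,flora_approx
gomphonema_micropus,Gomphonema micropus,Gomphonema,Gomphonemataceae,15,45,5,9,9,13,,,unknown,,flora_approx
gomphonema_olivaceum,Gomphonema olivaceum,Gomphonema,Gomphonemataceae,12,40,4,10,10,14,,,unknown,,flora_approx
amphora_lybica,Amphora lybica,Amphora,Catenulaceae,20,60,5,10,12,16,,,unknown,Amphora libyca,flora_approx
amphora_pediculus,Amphora pediculus,Amphora,Catenulaceae,7,15,2.5,5,16,22,,,unknown,,flora_approx
cymbella_excisa,Cymbella excisa,Cymbella,Cymbellaceae,20,45,7,12,8,13,,,unknown,,flora_approx
encyonema_caespitosum,Encyonema caespitosum,Encyonema,Cymbellaceae,15,50,6,14,8,13,,,unknown,,flora_approx
cymatopleura_elliptica,Cymatopleura elliptica,Cymatopleura,Surirellaceae,40,200,25,60,15,20,2,5,unknown,,flora_approx
cymatopleura_solea,Cymatopleura solea,Cymatopleura,Surirellaceae,30,300,12,40,15,20,6,9,unknown,,flora_approx
surirella_bifrons,Surirella bifrons,Surirella,Surirellaceae,40,150,15,40,,,1,3,unknown,,flora_approx
surirella_angusta,Surirella angusta,Surirella,Surirellaceae,15,70,5,15,,,5,8,unknown,,flora_approx
surirella_minuta,Surirella minuta,Surirella,Surirellaceae,10,40,5,15,,,5,9,unknown,,flora_approx
surirella_brebissonii,Surirella brebissonii,Surirella,Surirellaceae,10,70,10,30,,,4,8,unknown,,flora_approx
surirella_ovalis,Surirella ovalis,Surirella,Surirellaceae,20,70,15,40,,,3,6,unknown,,flora_approx
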