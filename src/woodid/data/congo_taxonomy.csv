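species,genus,family,n_samples
Afzelia africana,Afzelia,Fabaceae–Detarioideae,9
Afzelia bella,Afzelia,Fabaceae–Detarioideae,5
Afzelia bipindensis,Afzelia,Fabaceae–Detarioideae,8
Afzelia quanzensis,Afzelia,Fabaceae–Detarioideae,8
Afzelia pachyloba,Afzelia,Fabaceae–Detarioideae,8
Albizia adianthifolia,Albizia,Fabaceae–Caesalpinioideae,17
Albizia antunesiana,Albizia,Fabaceae–Caesalpinioideae,10
Albizia ferruginea,Albizia,Fabaceae–Caesalpinioideae,14
Alstonia boonei,Alstonia,Apocynaceae,12
Amphimas ferrugineus,Amphimas,Fabaceae–Papilionoideae,8
Amphimas pterocarpoides,Amphimas,Fabaceae–Papilionoideae,9
Anthonotha macrophylla,Anthonotha,Fabaceae–Detarioideae,7
Antiaris toxicaria,Antiaris,Moraceae,12
Antrocaryon nannanii,Antrocaryon,Anacardiaceae,17
Autranella congolensis,Autranella,Sapotaceae,8
Beilschmiedia congolana,Beilschmiedia,Lauraceae,10
Brachystegia laurentii,Brachystegia,Fabaceae–Detarioideae,7
Canarium schweinfurthii,Canarium,Burseraceae,13
Ceiba pentandra,Ceiba,Malvaceae,6
Celtis gomphophylla,Celtis,Cannabaceae,11
Chrysophyllum africanum,Chrysophyllum,Sapotaceae,4
Chrysophyllum lacourtianum,Chrysophyllum,Sapotaceae,8
Copaifera mildbraedii,Copaifera,Fabaceae–Detarioideae,13
Cordia platythyrsa,Cordia,Boraginaceae,8
Cynometra alexandri,Cynometra,Fabaceae–Detarioideae,15
Cynometra hankei,Cynometra,Fabaceae–Detarioideae,10
Diospyros crassiflora,Diospyros,Ebenaceae,10
Drypetes gossweileri,Drypetes,Euphorbiaceae,10
Ekebergia capensis,Ekebergia,Meliaceae,8
Entandrophragma angolense,Entandrophragma,Meliaceae,20
Entandrophragma candollei,Entandrophragma,Meliaceae,13
Entandrophragma cylindricum,Entandrophragma,Meliaceae,14
Entandrophragma utile,Entandrophragma,Meliaceae,17
Erythrophleum suaveolens,Erythrophleum,Fabaceae–Caesalpinioideae,6
Ficus mucuso,Ficus,Moraceae,8
Funtumia africana,Funtumia,Apocynaceae,15
Gilbertiodendron dewevrei,Gilbertiodendron,Fabaceae–Detarioideae,11
Guibourtia arnoldiana,Guibourtia,Fabaceae–Detarioideae,8
Guibourtia demeusei,Guibourtia,Fabaceae–Detarioideae,9
Mitragyna stipulosa,Mitragyna,Rubiaceae,17
Holoptelea grandis,Holoptelea,Ulmaceae,12
Irvingia grandifolia,Irvingia,Irvingiaceae,14
Khaya anthotheca,Khaya,Meliaceae,14
Klainedoxa gabonensis,Klainedoxa,Irvingiaceae,9
Leplaea cedrata,Leplaea,Meliaceae,15
Leplaea laurentii,Leplaea,Meliaceae,20
Leplaea thompsonii,Leplaea,Meliaceae,5
Lophira alata,Lophira,Ochnaceae,4
Lovoa trichilioides,Lovoa,Meliaceae,11
Mammea africana,Mammea,Clusiaceae,10
Milicia excelsa,Milicia,Moraceae,12
Millettia laurentii,Millettia,Fabaceae–Papilionoideae,10
Morus mesozygia,Morus,Moraceae,7
Musanga cecropioides,Musanga,Moraceae,12
Nauclea diderrichii,Nauclea,Rubiaceae,12
Nesogordonia kabingaensis,Nesogordonia,Malvaceae,8
Newtonia leucocarpa,Newtonia,Fabaceae–Caesalpinioideae,7
Ongokea gore,Ongokea,Olacaceae,10
Pentaclethra eetveldeana,Pentaclethra,Fabaceae–Caesalpinioideae,7
Pentaclethra macrophylla,Pentaclethra,Fabaceae–Caesalpinioideae,9
Pericopsis elata,Pericopsis,Fabaceae–Papilionoideae,5
Petersianthus macrocarpus,Petersianthus,Lecythidaceae,11
Piptadeniastrum africanum,Piptadeniastrum,Fabaceae–Caesalpinioideae,12
Pouteria aningeri,Pouteria,Sapotaceae,8
Prioria balsamifera,Prioria,Fabaceae–Detarioideae,12
Prioria oxyphylla,Prioria,Fabaceae–Detarioideae,14
Pterocarpus soyauxii,Pterocarpus,Fabaceae–Papilionoideae,17
Pterocarpus tinctorius,Pterocarpus,Fabaceae–Papilionoideae,10
Pycnanthus angolensis,Pycnanthus,Myristicaceae,4
Scorodophloeus zenkeri,Scorodophloeus,Fabaceae–Detarioideae,8
Staudtia kamerunensis,Staudtia,Myristicaceae,13
Terminalia superba,Terminalia,Combretaceae,9
Tessmannia africana,Tessmannia,Fabaceae–Detarioideae,13
Tieghemella heckelii,Tieghemella,Sapotaceae,9
Triplochiton scleroxylon,Triplochiton,Malvaceae,10
Zanthoxylum gilletii,Zanthoxylum,Rutaceae,7
Zanthoxylum lemairei,Zanthoxylum,Rutaceae,12
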