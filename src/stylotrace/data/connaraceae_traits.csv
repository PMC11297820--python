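taxon,state_5,state_binary
Agelaea_paradoxa,tristyly,trimorphism
Agelaea_pentagyna,tristyly,trimorphism
Cnestidium_rufescens,semihomostyly,trimorphism
Cnestis_bomiensis,,
Cnestis_ferruginea,homostyly,
Cnestis_palala,semihomostyly,trimorphism
Cnestis_polyphylla,semihomostyly,trimorphism
Cnestis_uncata,distyly,dimorphism
Pseudoconnarus_macrophyllus,semihomostyly,trimorphism
Rourea_acutipetala,distyly,dimorphism
Rourea_balansana,distyly,dimorphism
Rourea_calophylla,distyly,dimorphism
Rourea_coccinea,distyly,dimorphism
Rourea_minor_5329,distyly,dimorphism
Rourea_minor_2571,distyly,dimorphism
Rourea_myriantha,distyly,dimorphism
Rourea_orientalis,distyly,dimorphism
Rourea_parviflora,tristyly,trimorphism
Rourea_solanderi,tristyly,trimorphism
Rourea_thomsonii,distyly,dimorphism
Rourea_emarginata,distyly,dimorphism
Burttia_prunoides,distyly,dimorphism
Connarus_africanus,distyly,dimorphism
Connarus_cochinchinensis,distyly,dimorphism
Connarus_perrottetii,tristyly,trimorphism
Connarus_thonningii,distyly,dimorphism
Ellipanthus_beccarii,dioecy,
Ellipanthus_madagascariensis,distyly,dimorphism
Ellipanthus_razanatsimae,distyly,dimorphism
Hemandradenia_sp,distyly,dimorphism
Vismianthus_punctatus,distyly,dimorphism
Jollydora_armandui,tristyly,trimorphism
Jollydora_duparquetiana,tristyly,trimorphism
Manotes_expansa,tristyly,trimorphism
Manotes_macrantha,distyly,dimorphism
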