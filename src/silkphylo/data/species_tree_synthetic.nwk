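((((((((Argiope_argentata,(Argiope_bruennichi,Argiope_trifasciata)),(Araneus_ventricosus,Metepeira_grandiosa)),(Nephila_clavipes,(Nephila_clavata,Nephila_inaurata))),(Latrodectus_hesperus,Latrodectus_geometricus)),(Deinopis_spinosa,Uloborus_diversus)),(Agelenopsis_aperta,Euprosthenops_australis)),(Kukulkania_hibernalis,Diguetia_canities)),Bothriocyrtum_californicum);
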