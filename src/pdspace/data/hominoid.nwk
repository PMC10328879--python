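(((Pongo_abelii:1,Pongo_pygmaeus:1):1,((Gorilla_gorilla:1,Gorilla_beringei:1):1,(Homo_sapiens:1,(Pan_troglodytes:1,Pan_paniscus:1):1):1):1):1,(((Nomascus_hainanus:1,Nomascus_annamensis:1):1,((Nomascus_concolor:1,Nomascus_nasutus:1):1,(Nomascus_gabriellae:1,(Nomascus_leucogenys:1,Nomascus_siki:1):1):1):1):1,(Symphalangus_syndactylus:1,(((Hoolock_hoolock:1,Hoolock_leuconedys:1):1,(Hoolock_tianxing:1,Hoolock_sp:1):1):1,((Hylobates_klossii:1,Hylobates_albibarbis:1):1,((((Hylobates_lar:1,Hylobates_pileatus:1):1,Hylobates_agilis:1):1,Hylobates_muelleri:1):1,Hylobates_moloch:1):1):1):1):1):1);
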