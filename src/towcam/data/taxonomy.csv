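common_name,scientific_name,species,order,class
plain sand dollar,Echinarachnius parma,Echinarachnius parma,Clypeasteroida,Echinoidea
hermit crab sp.,Pagurus sp.,Pagurus sp.,Decapoda,Malacostraca
auger snail,Terebra dislocata,Terebra dislocata,Neogastropoda,Gastropoda
american sand lance,Ammodytes americanus,Ammodytes americanus,Perciformes,Actinopterygii
forbes sea star,Asterias forbesi,Asterias forbesi,Forcipulatida,Asteroidea
chestnut astarte clam,Astarte castanea,Astarte castanea,Carditida,Bivalvia
long-clawed hermit,Pagurus longicarpus,Pagurus longicarpus,Decapoda,Malacostraca
rock crab,Cancer irroratus,Cancer irroratus,Decapoda,Malacostraca
gulf stream flounder,Citharichthys arctifrons,Citharichthys arctifrons,Pleuronectiformes,Actinopterygii
northern sea robin,Prionotus carolinus,Prionotus carolinus,Scorpaeniformes,Actinopterygii
moon snail,Lunatia sp.,Lunatia sp.,Littorinimorpha,Gastropoda
warty nudibranch,Onchidoris sp.,Onchidoris sp.,Nudibranchia,Gastropoda
spotted hake,Urophycis regia,Urophycis regia,Gadiformes,Actinopterygii
sand shrimp,Crangon septemspinosa,Crangon septemspinosa,Decapoda,Malacostraca
unknown cancer crab,Cancer sp.,Cancer sp.,Decapoda,Malacostraca
anemone,Anemone unknown,Actiniaria indet.,Actiniaria,Anthozoa
lady crab,Ovalipes ocellatus,Ovalipes ocellatus,Decapoda,Malacostraca
sea cucumber,Pentamera sp.,Pentamera sp.,Dendrochirotida,Holothuroidea
clearnose skate,Raja eglanteria,Raja eglanteria,Rajiformes,Chondrichthyes
sea whip,Leptogorgia virgulata,Leptogorgia virgulata,Alcyonacea,Anthozoa
lined sea horse,Hippocampus erectus,Hippocampus erectus,Syngnathiformes,Actinopterygii
surf clam,Spisula solidissima,Spisula solidissima,Venerida,Bivalvia
unknown bony fish,Osteichthyes sp.,Osteichthyes indet.,Teleostei incertae sedis,Actinopterygii
windowpane flounder,Scophthalmus aquosus,Scophthalmus aquosus,Pleuronectiformes,Actinopterygii
black sea bass,Centropristis striata,Centropristis striata,Perciformes,Actinopterygii
four spot flounder,Paralichthys oblongus,Paralichthys oblongus,Pleuronectiformes,Actinopterygii
horseshoe crab,Limulus polyphemus,Limulus polyphemus,Xiphosurida,Merostomata
northern pipefish,Syngnathus fuscus,Syngnathus fuscus,Syngnathiformes,Actinopterygii
squid,Loligo or Illex sp.,Teuthida indet.,Teuthida,Cephalopoda
channeled whelk,Busycotypus canaliculatus,Busycotypus canaliculatus,Neogastropoda,Gastropoda
left-eyed flounder,Bothidae sp.,Bothidae indet.,Pleuronectiformes,Actinopterygii
unknown crabs,Crustacea sp.,Crustacea indet.,Decapoda,Malacostraca
winter skate,Leucoraja ocellata,Leucoraja ocellata,Rajiformes,Chondrichthyes
unknown polychaete,Polychaete sp.,Polychaeta indet.,Phyllodocida,Polychaeta
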