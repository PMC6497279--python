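common_name,scientific_name,beam_trawl,test_set,transects_1_7
plain sand dollar,Echinarachnius parma,6961,10,1294
hermit crab sp.,Pagurus sp.,464,249,882
auger snail,Terebra dislocata,296,0,0
american sand lance,Ammodytes americanus,29,0,231
forbes sea star,Asterias forbesi,165,48,85
chestnut astarte clam,Astarte castanea,29,0,213
long-clawed hermit,Pagurus longicarpus,0,0,159
rock crab,Cancer irroratus,134,0,4
gulf stream flounder,Citharichthys arctifrons,133,5,1
northern sea robin,Prionotus carolinus,30,5,52
moon snail,Lunatia sp.,12,0,63
warty nudibranch,Onchidoris sp.,61,0,14
spotted hake,Urophycis regia,50,0,0
sand shrimp,Crangon septemspinosa,43,0,0
unknown cancer crab,Cancer sp.,0,1,13
anemone,Anemone unknown,0,13,5
lady crab,Ovalipes ocellatus,5,0,0
sea cucumber,Pentamera sp.,5,0,0
clearnose skate,Raja eglanteria,0,0,4
sea whip,Leptogorgia virgulata,0,1,4
lined sea horse,Hippocampus erectus,3,0,0
surf clam,Spisula solidissima,3,0,0
unknown bony fish,Osteichthyes sp.,0,0,3
windowpane flounder,Scophthalmus aquosus,2,3,1
black sea bass,Centropristis striata,0,0,2
four spot flounder,Paralichthys oblongus,2,0,0
horseshoe crab,Limulus polyphemus,0,2,2
northern pipefish,Syngnathus fuscus,2,0,0
squid,Loligo or Illex sp.,2,1,0
channeled whelk,Busycotypus canaliculatus,0,1,1
left-eyed flounder,Bothidae sp.,0,0,1
unknown crabs,Crustacea sp.,0,1,1
winter skate,Leucoraja ocellata,1,0,0
unknown polychaete,Polychaete sp.,0,3,0
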