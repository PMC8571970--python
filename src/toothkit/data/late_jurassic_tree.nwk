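((Fruitadens:68,(Gargoyleosaurus:58,(Camptosaurus:38,Nanosaurus:38):20):10):15,((Ceratosaurus:38,Allosaurus:38):43,(((Apatosaurus:8,(Diplodocus:3,Tornieria:3):5):10,(Dicraeosaurus:8,Suuwassea:8):10):5,(Camarasaurus:13,Brachiosaurus:13):10):58):2):0;
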