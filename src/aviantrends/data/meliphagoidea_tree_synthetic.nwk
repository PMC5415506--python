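(('Spotted pardalote':0.75,('White-throated gerygone':0.6,('Weebill':0.45,('Buff-rumped thornbill':0.3,('Yellow thornbill':0.15,'Yellow-rumped thornbill':0.15):0.15):0.15):0.15):0.15):0.25,(((((('Yellow-tinted honeyeater':0.2,'White-plumed honeyeater':0.2):0.15,'Singing honeyeater':0.35):0.1,'Yellow-throated miner':0.45):0.1,'Yellow-tufted honeyeater':0.55):0.05,'White-eared honeyeater':0.6):0.05,(('New Holland honeyeater':0.5,'White-naped honeyeater':0.5):0.05,'Lewin''s honeyeater':0.55):0.1):0.35):0.0;
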