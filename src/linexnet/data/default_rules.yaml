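# Default biochemical rule set: lipid class registry, headgroup / acyl-
# transfer reactions of glycero-, glycerophospho- and sphingolipid
# metabolism with enzyme annotations, enabled chain-level reactions, and
# the pool of fatty acids considered available for acyl additions.
# Users override or extend this file via `extends: default`.
schema_version: 1
classes:
  - {name: PC,      chains: 2, backbone: glycerophospholipid}
  - {name: PE,      chains: 2, backbone: glycerophospholipid}
  - {name: PS,      chains: 2, backbone: glycerophospholipid}
  - {name: PI,      chains: 2, backbone: glycerophospholipid}
  - {name: PG,      chains: 2, backbone: glycerophospholipid}
  - {name: PA,      chains: 2, backbone: glycerophospholipid}
  - {name: LPC,     chains: 1, backbone: glycerophospholipid}
  - {name: LPE,     chains: 1, backbone: glycerophospholipid}
  - {name: LPS,     chains: 1, backbone: glycerophospholipid}
  - {name: LPI,     chains: 1, backbone: glycerophospholipid}
  - {name: LPG,     chains: 1, backbone: glycerophospholipid}
  - {name: LPA,     chains: 1, backbone: glycerophospholipid}
  - {name: PC O-,   chains: 2, backbone: glycerophospholipid}
  - {name: PE O-,   chains: 2, backbone: glycerophospholipid}
  - {name: LPC O-,  chains: 1, backbone: glycerophospholipid}
  - {name: LPE O-,  chains: 1, backbone: glycerophospholipid}
  - {name: CL,      chains: 4, backbone: glycerophospholipid}
  - {name: MG,      chains: 1, backbone: glycerolipid}
  - {name: DG,      chains: 2, backbone: glycerolipid}
  - {name: TG,      chains: 3, backbone: glycerolipid}
  - {name: Cer,     chains: 2, backbone: sphingolipid}
  - {name: SM,      chains: 2, backbone: sphingolipid}
  - {name: HexCer,  chains: 2, backbone: sphingolipid}
  - {name: Hex2Cer, chains: 2, backbone: sphingolipid}
  - {name: CE,      chains: 1, backbone: sterol}
class_reactions:
  # glycerophospholipid headgroup interconversions
  - {pair: [PC, PE], enzymes: [PEMT]}
  - {pair: [PE, PS], enzymes: [PISD, PTDSS2]}
  - {pair: [PC, PS], enzymes: [PTDSS1]}
  - {pair: [PA, PS], enzymes: []}
  - {pair: [PA, PC], enzymes: []}
  - {pair: [PA, PG], enzymes: [PGS1]}
  - {pair: [PA, PI], enzymes: [CDIPT]}
  - {pair: [PA, DG], enzymes: [LPIN1, DGKA]}
  - {pair: [PC O-, PE O-], enzymes: []}
  # acyl addition / removal within the glycerolipid backbone
  - {pair: [DG, TG], enzymes: [DGAT1, DGAT2, PNPLA2]}
  - {pair: [DG, MG], enzymes: [MGAT1, MGLL]}
  # lyso pairs (phospholipase A / acyltransferase remodeling)
  - {pair: [PC, LPC], enzymes: [PLA2G4A, LPCAT1]}
  - {pair: [PE, LPE], enzymes: [PLA2G4A, LPEAT1]}
  - {pair: [PS, LPS], enzymes: [PLA2G4A]}
  - {pair: [PI, LPI], enzymes: [PLA2G4A, MBOAT7]}
  - {pair: [PG, LPG], enzymes: [PLA2G4A]}
  - {pair: [PA, LPA], enzymes: [PLA2G4A, AGPAT1]}
  - {pair: [PC O-, LPC O-], enzymes: [PLA2G7]}
  - {pair: [PE O-, LPE O-], enzymes: [PLA2G7]}
  # sphingolipid headgroup metabolism
  - {pair: [Cer, SM], enzymes: [SGMS1, SMPD1]}
  - {pair: [Cer, HexCer], enzymes: [UGCG, GBA1]}
  - {pair: [HexCer, Hex2Cer], enzymes: [B4GALT5]}
fa_reactions: [elongation, desaturation, oxidation]
fa_pool:
  - "12:0"
  - "12:1"
  - "14:0"
  - "14:1"
  - "15:0"
  - "16:0"
  - "16:1"
  - "16:2"
  - "17:0"
  - "17:1"
  - "18:0"
  - "18:1"
  - "18:2"
  - "18:3"
  - "18:4"
  - "19:0"
  - "20:0"
  - "20:1"
  - "20:2"
  - "20:3"
  - "20:4"
  - "20:5"
  - "22:0"
  - "22:1"
  - "22:2"
  - "22:4"
  - "22:5"
  - "22:6"
  - "24:0"
  - "24:1"
  - "24:6"
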