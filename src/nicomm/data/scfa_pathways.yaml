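# Reconstructed SCFA-generation pathway for the ruminal microbiome, plus the
# auxiliary fatty-acid / nitrogen / sulfur pathways used in population
# comparisons.  Each sub-pathway lists pathway enzyme genes (PEGs); a PEG is
# one enzymatic step represented by a set of interchangeable KO ids.
#
# CURATED STAND-IN ROSTER: the PEG codes and the 10 sub-pathway layout follow
# the reconstruction; the KO membership per step is curated from general KEGG
# knowledge and is editable.  PEG codes 27-32 are shared between hemicellulose
# and pectin degradation; codes 44 and 46 are shared between propionate and
# acetate generation.
pathways:
  - id: scfa_generation
    name: SCFA generation
    subpathways:
      - name: Starch degradation
        pegs:
          - {code: 1, kos: [K01176]}          # alpha-amylase
          - {code: 2, kos: [K01178]}          # glucoamylase
          - {code: 3, kos: [K01200]}          # pullulanase
          - {code: 4, kos: [K01187]}          # alpha-glucosidase
          - {code: 5, kos: [K00691]}          # maltose phosphorylase
          - {code: 6, kos: [K00705]}          # 4-alpha-glucanotransferase
      - name: Glycolysis
        pegs:
          - {code: 7, kos: [K00844, K00845]}  # glucokinase
          - {code: 8, kos: [K01810]}          # glucose-6-phosphate isomerase
          - {code: 9, kos: [K00850]}          # 6-phosphofructokinase
          - {code: 10, kos: [K01623, K01624]} # fructose-bisphosphate aldolase
          - {code: 11, kos: [K01803]}         # triosephosphate isomerase
          - {code: 12, kos: [K00134]}         # GAPDH
          - {code: 13, kos: [K00927]}         # phosphoglycerate kinase
          - {code: 14, kos: [K01834, K15633]} # phosphoglycerate mutase
          - {code: 15, kos: [K01689]}         # enolase
          - {code: 16, kos: [K00873]}         # pyruvate kinase
      - name: Cellulose degradation
        pegs:
          - {code: 17, kos: [K01179]}         # endoglucanase
          - {code: 18, kos: [K01225]}         # cellobiohydrolase
          - {code: 19, kos: [K05349, K05350]} # beta-glucosidase
          - {code: 20, kos: [K00702]}         # cellobiose phosphorylase
      - name: Hemicellulose degradation
        pegs:
          - {code: 21, kos: [K01181]}         # endo-1,4-beta-xylanase
          - {code: 22, kos: [K01198]}         # beta-xylosidase
          - {code: 23, kos: [K01805]}         # xylose isomerase
          - {code: 24, kos: [K00854]}         # xylulokinase
          - {code: 25, kos: [K01209]}         # alpha-L-arabinofuranosidase
          - {code: 26, kos: [K01218]}         # endo-1,4-beta-mannosidase
          - {code: 27, kos: [K01213]}         # endo-1,5-alpha-L-arabinanase (shared)
          - {code: 28, kos: [K01190]}         # beta-galactosidase (shared)
          - {code: 29, kos: [K01804]}         # L-arabinose isomerase (shared)
          - {code: 30, kos: [K00853]}         # ribulokinase (shared)
          - {code: 31, kos: [K01784]}         # UDP-glucose 4-epimerase (shared)
          - {code: 32, kos: [K00849]}         # galactokinase (shared)
      - name: Pectin degradation
        pegs:
          - {code: 33, kos: [K01051]}         # pectinesterase
          - {code: 34, kos: [K01184]}         # polygalacturonase
          - {code: 35, kos: [K01728]}         # pectate lyase
          - {code: 36, kos: [K01730]}         # oligogalacturonide lyase
          - {code: 37, kos: [K00874]}         # 2-dehydro-3-deoxygluconokinase
          - {code: 38, kos: [K01625]}         # KDPG aldolase
          - {code: 27, kos: [K01213]}
          - {code: 28, kos: [K01190]}
          - {code: 29, kos: [K01804]}
          - {code: 30, kos: [K00853]}
          - {code: 31, kos: [K01784]}
          - {code: 32, kos: [K00849]}
      - name: Propionate generation
        pegs:
          - {code: 39, kos: [K01596]}                  # PEP carboxykinase
          - {code: 40, kos: [K00024, K00025]}          # malate dehydrogenase
          - {code: 41, kos: [K01676, K01679]}          # fumarate hydratase
          - {code: 42, kos: [K00244]}                  # fumarate reductase
          - {code: 43, kos: [K01847, K01848, K01849]}  # methylmalonyl-CoA mutase
          - {code: 44, kos: [K00625, K13788]}          # phosphotransacylase (shared)
          - {code: 45, kos: [K11264]}                  # methylmalonyl-CoA decarboxylase
          - {code: 46, kos: [K00925]}                  # acetate kinase (shared)
      - name: Butyrate generation
        pegs:
          - {code: 47, kos: [K00626]}          # acetyl-CoA C-acetyltransferase
          - {code: 48, kos: [K00074]}          # 3-hydroxybutyryl-CoA dehydrogenase
          - {code: 49, kos: [K01692, K17865]}  # crotonase
          - {code: 50, kos: [K00248]}          # butyryl-CoA dehydrogenase
          - {code: 51, kos: [K00634]}          # phosphate butyryltransferase
          - {code: 52, kos: [K00929]}          # butyrate kinase
          - {code: 53, kos: [K01034, K01035]}  # butyryl-CoA:acetate CoA-transferase
      - name: Acetate generation
        pegs:
          - {code: 54, kos: [K03737, K00169, K00170]}  # pyruvate:ferredoxin oxidoreductase
          - {code: 55, kos: [K01905]}                  # acetate-CoA ligase (ADP-forming)
          - {code: 56, kos: [K00132]}                  # acetaldehyde dehydrogenase
          - {code: 44, kos: [K00625, K13788]}
          - {code: 46, kos: [K00925]}
      - name: Formate generation
        pegs:
          - {code: 57, kos: [K00656]}          # pyruvate formate-lyase
          - {code: 58, kos: [K00122, K00123]}  # formate dehydrogenase
      - name: Lactate metabolism
        pegs:
          - {code: 59, kos: [K00016]}          # L-lactate dehydrogenase
          - {code: 60, kos: [K03778]}          # D-lactate dehydrogenase
          - {code: 61, kos: [K22373]}          # lactate racemase
          - {code: 62, kos: [K03303]}          # lactate permease
  - id: fatty_acid_biosynthesis
    name: Fatty acid biosynthesis
    subpathways:
      - name: Fatty acid biosynthesis
        pegs:
          - {code: 1, kos: [K01961, K01962, K01963]}  # acetyl-CoA carboxylase
          - {code: 2, kos: [K00645]}                  # malonyl-CoA:ACP transacylase
          - {code: 3, kos: [K00647, K09458]}          # 3-oxoacyl-ACP synthase
          - {code: 4, kos: [K00059]}                  # 3-oxoacyl-ACP reductase
          - {code: 5, kos: [K02372]}                  # 3-hydroxyacyl-ACP dehydratase
          - {code: 6, kos: [K00208]}                  # enoyl-ACP reductase
  - id: nitrogen_metabolism
    name: Nitrogen metabolism
    subpathways:
      - name: Dissimilatory nitrate reduction
        pegs:
          - {code: 1, kos: [K00370, K00371, K02567]}  # nitrate reductase
          - {code: 2, kos: [K00362, K00363, K03385]}  # nitrite reductase
      - name: Nitrogen fixation
        pegs:
          - {code: 3, kos: [K02586, K02588, K02591]}  # nitrogenase
  - id: sulfur_metabolism
    name: Sulfur metabolism
    subpathways:
      - name: Assimilatory sulfate reduction
        pegs:
          - {code: 1, kos: [K00956, K00957, K00958]}  # sulfate adenylyltransferase
          - {code: 2, kos: [K00390]}                  # PAPS/APS reductase
          - {code: 3, kos: [K00380, K00381]}          # sulfite reductase
      - name: Dissimilatory sulfate reduction
        pegs:
          - {code: 4, kos: [K00394, K00395]}          # APS reductase
          - {code: 5, kos: [K11180, K11181]}          # dissimilatory sulfite reductase
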