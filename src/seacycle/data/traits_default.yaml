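Fe_stress:
  system: KO
  genes:
  - id: K02012
    function: iron(III) transport system substrate-binding protein
  - id: K02013
    function: iron complex transport system ATP-binding protein
  - id: K02014
    function: iron complex outer membrane receptor protein
  - id: K02015
    function: iron complex transport system permease protein
  - id: K02016
    function: iron complex transport system substrate-binding protein
  - id: K23181
    function: siderophore uptake inner membrane transporter
N_stress:
  system: KO
  genes:
  - id: K01428
    function: urease alpha subunit urea hydrolysis
  - id: K01429
    function: urease beta subunit urea hydrolysis
  - id: K01430
    function: urease gamma subunit urea hydrolysis
  - id: K11959
    function: urea transport system substrate-binding protein
  - id: K02575
    function: nitrate nitrite transport protein
  - id: K00370
    function: nitrate reductase catalytic subunit
P_stress:
  system: KO
  genes:
  - id: K01077
    function: alkaline phosphatase phosphoester cleavage
  - id: K02036
    function: phosphate transport system ATP-binding protein
  - id: K02037
    function: phosphate transport system permease protein
  - id: K02038
    function: phosphate transport system permease protein PstA
  - id: K02040
    function: phosphate transport system substrate-binding protein
  - id: K05781
    function: phosphonate degradation carbon phosphorus lyase
C_degradation:
  system: Pfam
  genes:
  - id: PF00704
    function: glycoside hydrolase chitinase family
  - id: PF00331
    function: glycoside hydrolase xylanase family
  - id: PF00150
    function: cellulase glycoside hydrolase family
  - id: PF01915
    function: glycoside hydrolase beta glucosidase
  - id: PF00703
    function: glycoside hydrolase galactosidase family
  - id: PF02156
    function: glycoside hydrolase alpha glucuronidase
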