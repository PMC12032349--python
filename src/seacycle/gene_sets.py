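"""Built-in gene-family sets: nutrient-stress / carbon-degradation traits and
single-copy marker genes.

The trait sets are a small default curation sufficient for simulation and
testing — a stand-in for a full literature-curated list, organised the same
way (per-gene biochemical function strings; KO IDs for nutrient acquisition,
Pfam IDs for carbohydrate-active enzymes).  The 139 single-copy marker IDs
are synthetic Pfam-style placeholders (PF9xxxx, outside the real Pfam
accession range) used by the simulator and the average-genome-size
estimator.
"""

from __future__ import annotations

#: Iron acquisition / Fe-stress genes (KEGG Orthologs).
FE_STRESS_GENES = {
    "K02012": "iron(III) transport system substrate-binding protein",
    "K02013": "iron complex transport system ATP-binding protein",
    "K02014": "iron complex outer membrane receptor protein",
    "K02015": "iron complex transport system permease protein",
    "K02016": "iron complex transport system substrate-binding protein",
    "K23181": "siderophore uptake inner membrane transporter",
}

#: Nitrogen acquisition / N-stress genes (KEGG Orthologs).
N_STRESS_GENES = {
    "K01428": "urease alpha subunit urea hydrolysis",
    "K01429": "urease beta subunit urea hydrolysis",
    "K01430": "urease gamma subunit urea hydrolysis",
    "K11959": "urea transport system substrate-binding protein",
    "K02575": "nitrate nitrite transport protein",
    "K00370": "nitrate reductase catalytic subunit",
}

#: Phosphorus acquisition / P-stress genes (KEGG Orthologs).
P_STRESS_GENES = {
    "K01077": "alkaline phosphatase phosphoester cleavage",
    "K02036": "phosphate transport system ATP-binding protein",
    "K02037": "phosphate transport system permease protein",
    "K02038": "phosphate transport system permease protein PstA",
    "K02040": "phosphate transport system substrate-binding protein",
    "K05781": "phosphonate degradation carbon phosphorus lyase",
}

#: Organic-matter degradation genes, CAZyme-style (Pfam domains).
C_DEGRADATION_GENES = {
    "PF00704": "glycoside hydrolase chitinase family",
    "PF00331": "glycoside hydrolase xylanase family",
    "PF00150": "cellulase glycoside hydrolase family",
    "PF01915": "glycoside hydrolase beta glucosidase",
    "PF00703": "glycoside hydrolase galactosidase family",
    "PF02156": "glycoside hydrolase alpha glucuronidase",
}

TRAIT_GENE_SETS = {
    "Fe_stress": ("KO", FE_STRESS_GENES),
    "N_stress": ("KO", N_STRESS_GENES),
    "P_stress": ("KO", P_STRESS_GENES),
    "C_degradation": ("Pfam", C_DEGRADATION_GENES),
}

#: 139 universally single-copy marker gene families (synthetic Pfam-style
#: IDs; every simulated genome carries each exactly once).
SINGLE_COPY_MARKERS = tuple(f"PF9{i:04d}" for i in range(139))
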