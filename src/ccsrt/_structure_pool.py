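"""Curated structure pool backing the synthetic standards library.

Three chemical families are represented so that the pool has genuine cluster
structure in descriptor space, mirroring the class diversity of a commercial
metabolite standards plate:

* ``polar``    — amino acids, sugars and polyols, small organic acids,
                 amines and related water-soluble metabolites;
* ``aromatic`` — nucleosides, nucleobases, aromatic acids and other
                 heteroaromatic metabolites;
* ``lipid``    — fatty acids and derivatives (alcohols, amides, methyl
                 esters), built from a hand-curated core plus homologous
                 series templates.

All entries are (name, smiles, family); every SMILES parses with RDKit (there
is a test for this). Homologous series are expanded programmatically so the
pool exceeds 300 structures without shipping a large fixture file.
"""

from __future__ import annotations

_POLAR_CORE: list[tuple[str, str]] = [
    ("glycine", "NCC(=O)O"),
    ("L-alanine", "C[C@@H](N)C(=O)O"),
    ("L-serine", "OC[C@@H](N)C(=O)O"),
    ("L-threonine", "C[C@H](O)[C@@H](N)C(=O)O"),
    ("L-valine", "CC(C)[C@@H](N)C(=O)O"),
    ("L-leucine", "CC(C)C[C@@H](N)C(=O)O"),
    ("L-isoleucine", "CC[C@H](C)[C@@H](N)C(=O)O"),
    ("L-proline", "OC(=O)[C@@H]1CCCN1"),
    ("L-methionine", "CSCC[C@@H](N)C(=O)O"),
    ("L-cysteine", "SC[C@@H](N)C(=O)O"),
    ("L-aspartate", "OC(=O)C[C@@H](N)C(=O)O"),
    ("L-glutamate", "OC(=O)CC[C@@H](N)C(=O)O"),
    ("L-asparagine", "NC(=O)C[C@@H](N)C(=O)O"),
    ("L-glutamine", "NC(=O)CC[C@@H](N)C(=O)O"),
    ("L-lysine", "NCCCC[C@@H](N)C(=O)O"),
    ("L-arginine", "NC(=N)NCCC[C@@H](N)C(=O)O"),
    ("L-ornithine", "NCCC[C@@H](N)C(=O)O"),
    ("L-citrulline", "NC(=O)NCCC[C@@H](N)C(=O)O"),
    ("taurine", "NCCS(=O)(=O)O"),
    ("creatine", "CN(CC(=O)O)C(=N)N"),
    ("creatinine", "CN1CC(=O)N=C1N"),
    ("betaine", "C[N+](C)(C)CC(=O)[O-]"),
    ("carnitine", "C[N+](C)(C)C[C@H](O)CC(=O)[O-]"),
    ("choline", "C[N+](C)(C)CCO"),
    ("glycerophosphocholine", "C[N+](C)(C)CCOP(=O)([O-])OCC(O)CO"),
    ("D-glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("D-fructose", "OCC1(O)OC[C@@H](O)[C@@H](O)C1O"),
    ("D-galactose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@H]1O"),
    ("D-mannose", "OC[C@H]1OC(O)[C@@H](O)[C@@H](O)[C@@H]1O"),
    ("D-ribose", "OC[C@H]1OC(O)[C@H](O)[C@H]1O"),
    ("D-xylose", "OC[C@H]1OC(O)[C@H](O)[C@@H]1O"),
    ("sucrose", "OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O"),
    ("trehalose", "OC[C@H]1O[C@H](O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("lactose", "OC[C@H]1O[C@@H](O[C@H]2[C@H](O)[C@@H](O)C(O)O[C@@H]2CO)[C@H](O)[C@@H](O)[C@H]1O"),
    ("maltose", "OC[C@H]1O[C@H](O[C@H]2[C@H](O)[C@@H](O)C(O)O[C@@H]2CO)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("myo-inositol", "OC1C(O)C(O)C(O)C(O)C1O"),
    ("glucosamine", "NC1C(O)OC(CO)C(O)C1O"),
    ("N-acetylglucosamine", "CC(=O)NC1C(O)OC(CO)C(O)C1O"),
    ("gluconic acid", "OCC(O)C(O)C(O)C(O)C(=O)O"),
    ("glucuronic acid", "OC1OC(C(=O)O)C(O)C(O)C1O"),
    ("ascorbic acid", "OCC(O)C1OC(=O)C(O)=C1O"),
    ("citric acid", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("isocitric acid", "OC(C(CC(=O)O)C(=O)O)C(=O)O"),
    ("malic acid", "OC(CC(=O)O)C(=O)O"),
    ("fumaric acid", "OC(=O)/C=C/C(=O)O"),
    ("succinic acid", "OC(=O)CCC(=O)O"),
    ("alpha-ketoglutaric acid", "OC(=O)CCC(=O)C(=O)O"),
    ("oxaloacetic acid", "OC(=O)CC(=O)C(=O)O"),
    ("pyruvic acid", "CC(=O)C(=O)O"),
    ("lactic acid", "CC(O)C(=O)O"),
    ("glyceric acid", "OCC(O)C(=O)O"),
    ("glycolic acid", "OCC(=O)O"),
    ("oxalic acid", "OC(=O)C(=O)O"),
    ("malonic acid", "OC(=O)CC(=O)O"),
    ("tartaric acid", "OC(C(O)C(=O)O)C(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("glycerol 3-phosphate", "OCC(O)COP(=O)(O)O"),
    ("glucose 6-phosphate", "OC1OC(COP(=O)(O)O)C(O)C(O)C1O"),
    ("fructose 6-phosphate", "OCC1(O)OC(COP(=O)(O)O)C(O)C1O"),
    ("phosphoenolpyruvate", "OC(=O)C(=C)OP(=O)(O)O"),
    ("3-phosphoglycerate", "OCC(OP(=O)(O)O)C(=O)O"),
    ("glutathione", "NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O"),
    ("spermidine", "NCCCCNCCCN"),
    ("spermine", "NCCCNCCCCNCCCN"),
    ("putrescine", "NCCCCN"),
    ("cadaverine", "NCCCCCN"),
    ("ethanolamine", "NCCO"),
    ("phosphoethanolamine", "NCCOP(=O)(O)O"),
    ("GABA", "NCCCC(=O)O"),
    ("beta-alanine", "NCCC(=O)O"),
    ("sarcosine", "CNCC(=O)O"),
    ("dimethylglycine", "CN(C)CC(=O)O"),
    ("urea", "NC(N)=O"),
    ("allantoin", "NC(=O)NC1NC(=O)NC1=O"),
    ("pantothenic acid", "CC(C)(CO)C(O)C(=O)NCCC(=O)O"),
    ("S-adenosylhomocysteine precursor homocysteine", "OC(=O)C(N)CCS"),
    ("cystathionine", "NC(CCSCC(N)C(=O)O)C(=O)O"),
    ("methylmalonic acid", "CC(C(=O)O)C(=O)O"),
    ("3-hydroxybutyric acid", "CC(O)CC(=O)O"),
    ("acetoacetic acid", "CC(=O)CC(=O)O"),
    ("aminoadipic acid", "NC(CCCC(=O)O)C(=O)O"),
    ("threonic acid", "OCC(O)C(O)C(=O)O"),
]

_AROMATIC_CORE: list[tuple[str, str]] = [
    ("L-phenylalanine", "N[C@@H](Cc1ccccc1)C(=O)O"),
    ("L-tyrosine", "N[C@@H](Cc1ccc(O)cc1)C(=O)O"),
    ("L-tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O"),
    ("L-histidine", "N[C@@H](Cc1c[nH]cn1)C(=O)O"),
    ("adenine", "Nc1ncnc2[nH]cnc12"),
    ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
    ("cytosine", "Nc1cc[nH]c(=O)n1"),
    ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
    ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
    ("hypoxanthine", "O=c1[nH]cnc2[nH]cnc12"),
    ("xanthine", "O=c1[nH]c(=O)c2[nH]cnc2[nH]1"),
    ("uric acid", "O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1"),
    ("adenosine", "Nc1ncnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O"),
    ("guanosine", "Nc1nc2c(ncn2[C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)[nH]1"),
    ("cytidine", "Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)n1"),
    ("uridine", "OC[C@H]1O[C@@H](n2ccc(=O)[nH]c2=O)[C@H](O)[C@@H]1O"),
    ("thymidine", "Cc1cn([C@H]2C[C@H](O)[C@@H](CO)O2)c(=O)[nH]c1=O"),
    ("inosine", "OC[C@H]1O[C@@H](n2cnc3c2nc[nH]c3=O)[C@H](O)[C@@H]1O"),
    ("xanthosine", "OC[C@H]1O[C@@H](n2cnc3c2[nH]c(=O)[nH]c3=O)[C@H](O)[C@@H]1O"),
    ("AMP", "Nc1ncnc2c1ncn2[C@@H]1O[C@H](COP(=O)(O)O)[C@@H](O)[C@H]1O"),
    ("GMP", "Nc1nc2c(ncn2[C@@H]2O[C@H](COP(=O)(O)O)[C@@H](O)[C@H]2O)c(=O)[nH]1"),
    ("UMP", "O=c1ccn([C@@H]2O[C@H](COP(=O)(O)O)[C@@H](O)[C@H]2O)c(=O)[nH]1"),
    ("CMP", "Nc1ccn([C@@H]2O[C@H](COP(=O)(O)O)[C@@H](O)[C@H]2O)c(=O)n1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("nicotinic acid", "OC(=O)c1cccnc1"),
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("trigonelline", "C[n+]1cccc(C(=O)[O-])c1"),
    ("pyridoxine", "Cc1ncc(CO)c(CO)c1O"),
    ("pyridoxal", "Cc1ncc(CO)c(C=O)c1O"),
    ("thiamine", "Cc1ncc(C[n+]2csc(CCO)c2C)c(N)n1"),
    ("riboflavin", "Cc1cc2nc3c(=O)[nH]c(=O)nc-3n(CC(O)C(O)C(O)CO)c2cc1C"),
    ("folic acid", "Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1"),
    ("biotin", "O=C1N[C@H]2CS[C@@H](CCCCC(=O)O)[C@H]2N1"),
    ("hippuric acid", "OC(=O)CNC(=O)c1ccccc1"),
    ("benzoic acid", "OC(=O)c1ccccc1"),
    ("salicylic acid", "OC(=O)c1ccccc1O"),
    ("4-hydroxybenzoic acid", "OC(=O)c1ccc(O)cc1"),
    ("vanillic acid", "COc1cc(C(=O)O)ccc1O"),
    ("ferulic acid", "COc1cc(/C=C/C(=O)O)ccc1O"),
    ("caffeic acid", "OC(=O)/C=C/c1ccc(O)c(O)c1"),
    ("p-coumaric acid", "OC(=O)/C=C/c1ccc(O)cc1"),
    ("cinnamic acid", "OC(=O)/C=C/c1ccccc1"),
    ("phenylacetic acid", "OC(=O)Cc1ccccc1"),
    ("phenyllactic acid", "OC(Cc1ccccc1)C(=O)O"),
    ("phenylpyruvic acid", "O=C(Cc1ccccc1)C(=O)O"),
    ("homovanillic acid", "COc1cc(CC(=O)O)ccc1O"),
    ("indole-3-acetic acid", "OC(=O)Cc1c[nH]c2ccccc12"),
    ("indole-3-lactic acid", "OC(Cc1c[nH]c2ccccc12)C(=O)O"),
    ("indole-3-propionic acid", "OC(=O)CCc1c[nH]c2ccccc12"),
    ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
    ("tryptamine", "NCCc1c[nH]c2ccccc12"),
    ("melatonin", "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"),
    ("dopamine", "NCCc1ccc(O)c(O)c1"),
    ("tyramine", "NCCc1ccc(O)cc1"),
    ("epinephrine", "CNCC(O)c1ccc(O)c(O)c1"),
    ("norepinephrine", "NCC(O)c1ccc(O)c(O)c1"),
    ("histamine", "NCCc1c[nH]cn1"),
    ("kynurenine", "NC(Cc1ccccc1N)C(=O)O" if False else "NC(CC(=O)c1ccccc1N)C(=O)O"),
    ("kynurenic acid", "OC(=O)c1cc(O)c2ccccc2n1"),
    ("quinolinic acid", "OC(=O)c1cccnc1C(=O)O"),
    ("anthranilic acid", "Nc1ccccc1C(=O)O"),
    ("picolinic acid", "OC(=O)c1ccccn1"),
    ("urocanic acid", "OC(=O)/C=C/c1c[nH]cn1"),
    ("gentisic acid", "OC(=O)c1cc(O)ccc1O"),
    ("protocatechuic acid", "OC(=O)c1ccc(O)c(O)c1"),
    ("gallic acid", "OC(=O)c1cc(O)c(O)c(O)c1"),
    ("syringic acid", "COc1cc(C(=O)O)cc(OC)c1O"),
    ("3-methylhistidine", "Cn1cnc(CC(N)C(=O)O)c1"),
    ("carnosine", "NCCC(=O)NC(Cc1c[nH]cn1)C(=O)O"),
    ("5-hydroxyindoleacetic acid", "OC(=O)Cc1c[nH]c2ccc(O)cc12"),
    ("paraxanthine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("orotic acid", "OC(=O)c1cc(=O)[nH]c(=O)[nH]1"),
]

_LIPID_CORE: list[tuple[str, str]] = [
    ("oleic acid", "CCCCCCCC/C=C\\CCCCCCCC(=O)O"),
    ("linoleic acid", "CCCCC/C=C\\C/C=C\\CCCCCCCC(=O)O"),
    ("alpha-linolenic acid", "CC/C=C\\C/C=C\\C/C=C\\CCCCCCCC(=O)O"),
    ("arachidonic acid", "CCCCC/C=C\\C/C=C\\C/C=C\\C/C=C\\CCCC(=O)O"),
    ("palmitoleic acid", "CCCCCC/C=C\\CCCCCCCC(=O)O"),
    ("oleamide", "CCCCCCCC/C=C\\CCCCCCCC(N)=O"),
    ("monopalmitin", "CCCCCCCCCCCCCCCC(=O)OCC(O)CO"),
    ("monoolein", "CCCCCCCC/C=C\\CCCCCCCC(=O)OCC(O)CO"),
    ("palmitoylcarnitine", "CCCCCCCCCCCCCCCC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
    ("octanoylcarnitine", "CCCCCCCC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
    ("acetylcarnitine", "CC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
    ("sphingosine", "CCCCCCCCCCCCC/C=C/C(O)C(N)CO"),
    ("cholesterol", "CC(C)CCC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)[C@H]3CC[C@]12C"),
    ("cholic acid", "C[C@H](CCC(=O)O)[C@H]1CC[C@H]2[C@@H]3[C@H](O)C[C@@H]4C[C@H](O)CC[C@]4(C)[C@H]3C[C@H](O)[C@]12C"),
    ("deoxycholic acid", "C[C@H](CCC(=O)O)[C@H]1CC[C@H]2[C@@H]3CC[C@@H]4C[C@H](O)CC[C@]4(C)[C@H]3C[C@H](O)[C@]12C"),
    ("lithocholic acid", "C[C@H](CCC(=O)O)[C@H]1CC[C@H]2[C@@H]3CC[C@@H]4C[C@H](O)CC[C@]4(C)[C@H]3CC[C@]12C"),
    ("prostaglandin E2", "CCCCC[C@H](O)/C=C/[C@H]1[C@H](O)CC(=O)[C@@H]1C/C=C\\CCCC(=O)O"),
    ("12-HETE", "CCCCC/C=C\\CC(O)/C=C/C=C\\C/C=C\\CCCC(=O)O"),
    ("LPC 16:0", "CCCCCCCCCCCCCCCC(=O)OC[C@H](O)COP(=O)([O-])OCC[N+](C)(C)C"),
    ("LPE 18:1", "CCCCCCCC/C=C\\CCCCCCCC(=O)OC[C@H](O)COP(=O)(O)OCCN"),
]


def _chain(n: int) -> str:
    return "C" * n


def _homologous_series() -> list[tuple[str, str, str]]:
    """Template-generated homologous series (all tagged with their family)."""
    out: list[tuple[str, str, str]] = []
    # saturated fatty acids C4..C26
    for n in range(4, 27):
        out.append((f"fatty acid C{n}:0", _chain(n - 1) + "C(=O)O", "lipid"))
    # fatty alcohols C6..C22
    for n in range(6, 23):
        out.append((f"fatty alcohol C{n}", _chain(n) + "O", "lipid"))
    # fatty acid methyl esters C8..C20
    for n in range(8, 21):
        out.append((f"methyl ester C{n}:0", _chain(n - 1) + "C(=O)OC", "lipid"))
    # primary fatty amides C8..C20
    for n in range(8, 21):
        out.append((f"fatty amide C{n}:0", _chain(n - 1) + "C(N)=O", "lipid"))
    # dicarboxylic acids C5..C14 (polar; C4 = succinic acid is in the core)
    for n in range(5, 15):
        out.append((f"dicarboxylic acid C{n}", "OC(=O)" + _chain(n - 2) + "C(=O)O", "polar"))
    # 2-hydroxy acids C4..C10 (polar; C3 = lactic acid is in the core)
    for n in range(4, 11):
        out.append((f"2-hydroxy acid C{n}", _chain(n - 2) + "C(O)C(=O)O", "polar"))
    # 2-oxo acids C4..C10 (polar)
    for n in range(4, 11):
        out.append((f"2-oxo acid C{n}", _chain(n - 2) + "C(=O)C(=O)O", "polar"))
    # linear polyols (alditol-like) C4..C8 (polar; glycerol is in the core)
    for n in range(4, 9):
        out.append((f"polyol C{n}", "OC" + "C(O)" * (n - 2) + "CO", "polar"))
    # alpha,omega-alkanediols C4..C10 (polar)
    for n in range(4, 11):
        out.append((f"alkanediol C{n}", "O" + _chain(n) + "O", "polar"))
    # oligoglycines 2..6 residues (polar)
    for n in range(2, 7):
        out.append((f"oligoglycine n={n}", "NCC(=O)" + "NCC(=O)" * (n - 2) + "NCC(=O)O", "polar"))
    # omega-amino acids C5..C10 (polar; C3/C4 beta-alanine and GABA in the core)
    for n in range(5, 11):
        out.append((f"omega-amino acid C{n}", "N" + _chain(n - 1) + "C(=O)O", "polar"))
    # methylxanthine-like N-alkyl uracils (aromatic)
    for n in range(1, 6):
        out.append((f"N-alkyl uracil C{n}", "O=c1ccn(" + _chain(n) + ")c(=O)[nH]1", "aromatic"))
    # 4-alkylbenzoic acids (aromatic)
    for n in range(1, 7):
        out.append((f"4-alkylbenzoic acid C{n}", "OC(=O)c1ccc(" + _chain(n) + ")cc1", "aromatic"))
    # omega-phenylalkanoic acids C3..C8 (aromatic; C2 = phenylacetic in the core)
    for n in range(3, 9):
        out.append((f"phenylalkanoic acid C{n}",
                    "OC(=O)" + _chain(n - 2) + "c1ccccc1", "aromatic"))
    # indole-3-alkanoic acids C4..C7 (aromatic; shorter members are in the core)
    for n in range(4, 8):
        out.append((f"indole-3-alkanoic acid C{n}",
                    "OC(=O)" + _chain(n - 1) + "c1c[nH]c2ccccc12", "aromatic"))
    return out


def structure_pool() -> list[tuple[str, str, str]]:
    """The full pool as (name, smiles, family) tuples; order is fixed.

    Entries whose canonical structure duplicates an earlier entry are dropped,
    so every structure appears exactly once.
    """
    from rdkit import Chem

    raw = [(n, s, "polar") for n, s in _POLAR_CORE]
    raw += [(n, s, "aromatic") for n, s in _AROMATIC_CORE]
    raw += [(n, s, "lipid") for n, s in _LIPID_CORE]
    raw += _homologous_series()
    pool: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for name, smi, fam in raw:
        can = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if can in seen:
            continue
        seen.add(can)
        pool.append((name, smi, fam))
    return pool
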