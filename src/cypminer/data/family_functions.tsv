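family	known_function
CYP105	Xenobiotic degradation/biotransformation and secondary-metabolite biosynthesis
CYP107	Secondary-metabolite biosynthesis, including oxidative rearrangements in ansamycin/saliniketal pathways
CYP113	Macrolide antibiotic biosynthesis (erythromycin, tylosin, himastatin)
CYP124	Terminal hydroxylation of methyl-branched lipids
CYP125	Cholesterol and cholest-4-en-3-one hydroxylation
CYP146	beta-Hydroxytyrosine formation, a vancomycin-class precursor step
CYP154	Regio- and stereo-selective steroid hydroxylation; O-dealkylation/ortho-hydroxylation
CYP161	Polyene antibiotic biosynthesis (pimaricin, amphotericin)
CYP162	Peptidyl-nucleoside antibiotic (nikkomycin) biosynthesis
CYP163	Aminocoumarin (novobiocin) and skyllamycin biosynthesis
CYP244	Rapamycin-class polyketide tailoring (acts with CYP245)
CYP245	Rapamycin-class polyketide tailoring (acts with CYP244)
CYP248	Aureothin polyketide biosynthesis
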