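gene	eif2a_target	function
TOS1	+	Covalently-bound cell wall protein of unknown function
LRE1		Protein involved in control of cell wall structure and stress response
SCW4	+	Cell wall protein with similarity to glucanases
DSE2	+	Daughter cell-specific secreted protein, similarity to glucanases
SIM1	+	Protein of the SUN family
HSL1		Septin-binding kinase that localizes to the bud neck septin ring
UTH1	+	Mitochondrial inner membrane protein implicated in cell wall biogenesis
MMR1		Mitochondrial Myo2p Receptor-related
CTS1	+	Endochitinase
SUN4	+	Cell wall protein related to glucanases localized in birth scars
SRL1	+	Mannoprotein that exhibits a tight association with the cell wall
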