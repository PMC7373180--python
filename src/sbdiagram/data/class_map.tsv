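# Bidirectional vocabulary map between the internal model, SBO terms,
# SBGN Process Description glyph/arc classes and CellDesigner type strings.
# Transcribed from the SBGN PD level 1 specification's SBO mapping tables
# (version 1.3) and the Systems Biology Ontology; CellDesigner strings follow
# the 4.x extension vocabulary.
# One row per internal vocabulary item; "-" marks an empty cell.  Reverse
# lookups must stay deterministic, so a PD class or CellDesigner string
# appears in at most one row; internal items with no PD class of their own
# (gene, rna, receptor, ion, transport, influences) leave the cell empty and
# are sent through the documented fallback map in mapping.py instead.
#
# kind	internal	sbo	sbgn	celldesigner
element	macromolecule	SBO:0000245	macromolecule	PROTEIN
element	simple-chemical	SBO:0000247	simple chemical	SIMPLE_MOLECULE
element	nucleic-acid-feature	SBO:0000354	nucleic acid feature	-
element	gene	SBO:0000243	-	GENE
element	rna	SBO:0000250	-	RNA
element	receptor	SBO:0000244	-	RECEPTOR
element	ion	SBO:0000327	-	ION
element	phenotype	SBO:0000358	phenotype	PHENOTYPE
element	complex	SBO:0000253	complex	COMPLEX
element	unspecified	SBO:0000285	unspecified entity	UNKNOWN
element	source-sink	SBO:0000291	source and sink	DEGRADED
reaction	state-transition	SBO:0000176	process	STATE_TRANSITION
reaction	transport	SBO:0000185	-	TRANSPORT
reaction	known-transition-omitted	SBO:0000397	omitted process	KNOWN_TRANSITION_OMITTED
reaction	unknown-transition	SBO:0000396	uncertain process	UNKNOWN_TRANSITION
reaction	association	SBO:0000177	association	HETERODIMER_ASSOCIATION
reaction	dissociation	SBO:0000180	dissociation	DISSOCIATION
reaction	positive-influence	SBO:0000170	-	POSITIVE_INFLUENCE
reaction	negative-influence	SBO:0000169	-	NEGATIVE_INFLUENCE
reaction	unknown	SBO:0000375	-	-
role	substrate	SBO:0000010	consumption	-
role	side-substrate	SBO:0000603	-	-
role	product	SBO:0000011	production	-
role	side-product	SBO:0000604	-	-
role	modifier	SBO:0000019	modulation	MODULATION
role	activator	SBO:0000459	stimulation	PHYSICAL_STIMULATION
role	inhibitor	SBO:0000020	inhibition	INHIBITION
role	undefined	-	-	-
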