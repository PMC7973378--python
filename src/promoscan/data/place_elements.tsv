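pattern	element_name	description	source
CACGTG	G box	G box / binding site for AtMYC2	consensus core
CACGTA	ABRE	abscisic acid-responsive element (ACGT core)	consensus core
ACGT	ACGT element	ACGT / desiccation-responsive element	consensus core
GGCCCA	site II element	found in promoter regions of Arabidopsis cytochrome genes (Cytc-1, Cytc-2); overrepresented in promoters of nuclear genes encoding oxidative phosphorylation components	consensus core
GTAC	CuRE core	GTAC core of the copper-response element found in Chlamydomonas Cyc6 and Cpx1 genes; also involved in their oxygen response	consensus core
TACGTA	A box	A-box class ACGT element; found in the ocs gene	consensus core
CACT	Mem1	CACT tetranucleotide, key component of mesophyll expression module 1 in the distal cis-regulatory element of the F. trinervia ppcA1 gene	consensus core
AATATT	rolD motif	motif found in promoters of the root-specific rolD gene of Agrobacterium rhizogenes	consensus core
CTAATA	cytokinin-response motif	sequence critical for cytokinin-enhanced protein binding in vitro, found in the cucumber POR promoter	consensus core
CAAT	legA CAAT box	CAAT promoter consensus sequence found in the legA gene of pea	consensus core
GTCATA	W box	W box / binding site for WRKY3 and WRKY6	curated hexamer
ATTATC	GT-1 consensus	consensus GT-1 binding site found in many light-regulated genes	curated hexamer
ATAGTA	Mem1	hexamer assigned to the CACT module of mesophyll expression module 1 (ppcA1)	curated hexamer
AATACT	Mem1	hexamer assigned to the CACT module of mesophyll expression module 1 (ppcA1)	curated hexamer
GTAGTA	Mem1	hexamer assigned to the CACT module of mesophyll expression module 1 (ppcA1)	curated hexamer
TAAGTA	Mem1	hexamer assigned to the CACT module of mesophyll expression module 1 (ppcA1)	curated hexamer
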