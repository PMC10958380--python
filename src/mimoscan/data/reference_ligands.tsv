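# Stimulatory ligand family of the Va3S1/Vb13S1 TCR used to derive the
# recognition motif.  wheat-1 and wheat-2 are published environmental
# ligand sequences; FALK is the published HLA-C*06:02-binding control
# peptide (motif-negative).  All rows labelled "synthetic mimotope" are
# synthetic stand-ins sampled from the recognition motif so that every
# allowed residue at P5, P7 and P9 is observed at least once; they are not
# experimental sequences.
sequence	register	stimulatory	activation	source
LRMRRCRRM	nonamer	true	0.85	wheat-1 (Triticum aestivum RCG1B)
VRAGRVLRV	nonamer	true	0.80	wheat-2 (Triticum aestivum CFC21_050201)
ARAANALRL	nonamer	true	0.70	synthetic mimotope
GRGGQGRRF	nonamer	true	0.65	synthetic mimotope
SRSSRSLRI	nonamer	true	0.75	synthetic mimotope
VRHDGGNVL	nonamer	false	0.02	FALK control peptide
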