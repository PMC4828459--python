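accession	description
Potri.008G082100.1	ALA-interacting subunit 1, ALIS1
Potri.012G131300.1	Amino acid transporter 1
Potri.004G182800.1	BR-signaling kinase 1
Potri.005G234900.1	Calcium-binding tetratricopeptide protein
Potri.012G108200.1	Calcium-dependent phospholipid-binding family protein
Potri.011G003400.1	Calcium Dependent Protein Kinase 21
Potri.009G052700.1	Calcium Dependent Protein Kinase 7
Potri.018G096700.1	Diacylglycerol Kinase 3
Potri.006G174700.1	Diacylglycerol Kinase 7
Potri.001G012000.1	Glucan Synthase like-10
Potri.001G011900.1	Glucan Synthase like-10
Potri.015G089300.1	Glucan Synthase like-8
Potri.012G070500.1	Band 7 family protein
Potri.017G078100.1	Band 7 family protein
Potri.018G074300.1	Leucine Rich Repeat Protein Kinase
Potri.016G126300.1	Leucine Rich Repeat Protein Kinase
Potri.007G065000.1	Leucine-rich repeat family protein
Potri.006G081400.1	Protein phosphatase 2C
Potri.015G073000.1	ROP10
Potri.012G044600.1	Leucine Rich Repeat Protein Kinase
Potri.002G157700.1	Remorin
Potri.014G081300.1	Remorin
Potri.016G088200.1	SNARE/SYP71
Potri.009G015100.1	Tetraspanin 3
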