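family_label	kinase_class	accession
1	4	Potri.009G012900.1
2	1	Potri.003G032100.1
3	1	Potri.012G055500.1
4	1	Potri.018G081300.1
5	1	Potri.011G045600.1
Ca-dep PK	4	Potri.010G244800.1
Ca-dep PK	4	Potri.016G117200.1
Ca-dep PK	4	Potri.011G003400.1
Ca-dep PK	4	Potri.012G071700.1
Ca-dep PK	4	Potri.004G207300.1
Ca-dep PK	4	Potri.009G052700.1
Ca-dep PK	4	Potri.001G257100.1
LRR-PK	1	Potri.015G035500.1
LRR-PK	1	Potri.012G044600.1
LRR-PK	1	Potri.018G074300.1
LRR-PK	1	Potri.008G144900.1
LRR-PK	1	Potri.010G097200.1
LRR-PK	1	Potri.018G141000.1
LRR-PK	1	Potri.016G126300.1
LRR-PK	1	Potri.014G195100.1
PK	2	Potri.004G064400.1
PK	2	Potri.001G343900.1
PK	2	Potri.012G079000.1
PK	2	Potri.018G001800.1
PK	2	Potri.008G156000.1
RLCKII	1	Potri.004G182800.1
RLCKII	1	Potri.005G249300.1
RLCKII	1	Potri.002G011800.1
RLCKII	1	Potri.014G179300.1
RLCKII	1	Potri.014G082400.1
RLCKII	1	Potri.001G246400.1
RLCKII	1	Potri.003G126700.1
RLCKII	1	Potri.001G104700.1
RLCKII	1	Potri.016G105800.1
RLCKII	1	Potri.006G093900.2
RLCKVII	1	Potri.008G205700.1
RLCKVII	1	Potri.018G134100.1
RLCKVII	1	Potri.008G056400.1
RLCKVII	1	Potri.016G094300.1
RLCKVII	1	Potri.008G148000.1
RLCKVII	1	Potri.007G062700.1
RLCKVIII	1	Potri.017G036300.1
RLCKVIII	1	Potri.007G124000.1
RLCKVIII	1	Potri.014G114200.1
RLPK	1	Potri.001G234200.1
RLPK	1	Potri.010G213200.1
RLPK	1	Potri.001G405500.1
S-domain Kinase	1	Potri.001G385200.1
S-domain Kinase	1	Potri.001G438400.1
S-domain Kinase	1	Potri.011G112000.1
ST-PK	5	Potri.012G057300.1
ST-PK	5	Potri.015G055200.1
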