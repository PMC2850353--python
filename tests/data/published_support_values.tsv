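clade	comb	comb WO	comb BS	GHR	GHR WO	GHR BS	morph	morph WO	morph BS	indel	indel WO	indel BS	HBS
a	957	970	13	591	593	2	331	340	9	8	8	0	2
b	957	1004	47	591	605	14	331	344	13	8	8	0	20
c	957	958	1	591	592	1	333	331	-2	8	8	0	2
d	957	958	1	593	591	-2	334	331	-3	8	8	0	6
e	957	959	2	591	592	1	333	331	-2	8	8	0	3
f	957	958	1	591	592	1	336	331	-5	8	8	0	5
g	957	958	1	593	591	-2	333	331	-2	8	8	0	5
h	957	958	1	593	591	-2	331	331	0	8	8	0	3
i	957	962	5	591	592	1	331	334	3	8	9	1	0
j	957	962	5	591	594	3	331	331	0	8	8	0	2
k	957	958	1	591	593	2	334	332	-2	8	8	0	1
l	957	958	1	591	595	4	335	331	-4	8	8	0	1
m	957	963	6	591	596	5	331	332	1	8	8	0	0
n	957	958	1	591	592	1	331	332	1	8	8	0	-1
o	957	966	9	591	596	5	331	337	6	8	8	0	-2
p	957	990	33	591	615	24	331	338	7	8	8	0	2
q	957	978	21	591	613	22	338	331	-7	8	8	0	6
r	957	971	14	591	600	9	331	335	4	8	8	0	1
s	957	958	1	593	591	-2	331	334	3	8	8	0	0
t	957	970	13	591	601	10	331	335	4	8	8	0	-1
u	957	963	6	591	597	6	336	331	-5	8	8	0	5
v	957	959	2	591	592	1	337	331	-6	8	8	0	7
w	957	968	11	591	601	10	335	331	-4	8	8	0	5
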