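# Synthetic CFD penalty table (structure-compatible stand-in; replace with
# empirically derived penalties for production use).
# 4-field rows: position (1=5'-distal .. 20=PAM-proximal), spacer base,
#               genomic protospacer base, penalty in [0,1]
# 2-field rows: concrete PAM trinucleotide, penalty in [0,1]
1	A	A	1.0
1	A	C	0.6266
1	A	G	0.964
1	A	T	0.6266
1	C	A	0.6266
1	C	C	1.0
1	C	G	0.6266
1	C	T	0.964
1	G	A	0.964
1	G	C	0.6266
1	G	G	1.0
1	G	T	0.6266
1	T	A	0.6266
1	T	C	0.964
1	T	G	0.6266
1	T	T	1.0
2	A	A	1.0
2	A	C	0.6032
2	A	G	0.928
2	A	T	0.6032
2	C	A	0.6032
2	C	C	1.0
2	C	G	0.6032
2	C	T	0.928
2	G	A	0.928
2	G	C	0.6032
2	G	G	1.0
2	G	T	0.6032
2	T	A	0.6032
2	T	C	0.928
2	T	G	0.6032
2	T	T	1.0
3	A	A	1.0
3	A	C	0.5798
3	A	G	0.892
3	A	T	0.5798
3	C	A	0.5798
3	C	C	1.0
3	C	G	0.5798
3	C	T	0.892
3	G	A	0.892
3	G	C	0.5798
3	G	G	1.0
3	G	T	0.5798
3	T	A	0.5798
3	T	C	0.892
3	T	G	0.5798
3	T	T	1.0
4	A	A	1.0
4	A	C	0.5564
4	A	G	0.856
4	A	T	0.5564
4	C	A	0.5564
4	C	C	1.0
4	C	G	0.5564
4	C	T	0.856
4	G	A	0.856
4	G	C	0.5564
4	G	G	1.0
4	G	T	0.5564
4	T	A	0.5564
4	T	C	0.856
4	T	G	0.5564
4	T	T	1.0
5	A	A	1.0
5	A	C	0.533
5	A	G	0.82
5	A	T	0.533
5	C	A	0.533
5	C	C	1.0
5	C	G	0.533
5	C	T	0.82
5	G	A	0.82
5	G	C	0.533
5	G	G	1.0
5	G	T	0.533
5	T	A	0.533
5	T	C	0.82
5	T	G	0.533
5	T	T	1.0
6	A	A	1.0
6	A	C	0.5096
6	A	G	0.784
6	A	T	0.5096
6	C	A	0.5096
6	C	C	1.0
6	C	G	0.5096
6	C	T	0.784
6	G	A	0.784
6	G	C	0.5096
6	G	G	1.0
6	G	T	0.5096
6	T	A	0.5096
6	T	C	0.784
6	T	G	0.5096
6	T	T	1.0
7	A	A	1.0
7	A	C	0.4862
7	A	G	0.748
7	A	T	0.4862
7	C	A	0.4862
7	C	C	1.0
7	C	G	0.4862
7	C	T	0.748
7	G	A	0.748
7	G	C	0.4862
7	G	G	1.0
7	G	T	0.4862
7	T	A	0.4862
7	T	C	0.748
7	T	G	0.4862
7	T	T	1.0
8	A	A	1.0
8	A	C	0.4628
8	A	G	0.712
8	A	T	0.4628
8	C	A	0.4628
8	C	C	1.0
8	C	G	0.4628
8	C	T	0.712
8	G	A	0.712
8	G	C	0.4628
8	G	G	1.0
8	G	T	0.4628
8	T	A	0.4628
8	T	C	0.712
8	T	G	0.4628
8	T	T	1.0
9	A	A	1.0
9	A	C	0.4394
9	A	G	0.676
9	A	T	0.4394
9	C	A	0.4394
9	C	C	1.0
9	C	G	0.4394
9	C	T	0.676
9	G	A	0.676
9	G	C	0.4394
9	G	G	1.0
9	G	T	0.4394
9	T	A	0.4394
9	T	C	0.676
9	T	G	0.4394
9	T	T	1.0
10	A	A	1.0
10	A	C	0.416
10	A	G	0.64
10	A	T	0.416
10	C	A	0.416
10	C	C	1.0
10	C	G	0.416
10	C	T	0.64
10	G	A	0.64
10	G	C	0.416
10	G	G	1.0
10	G	T	0.416
10	T	A	0.416
10	T	C	0.64
10	T	G	0.416
10	T	T	1.0
11	A	A	1.0
11	A	C	0.3926
11	A	G	0.604
11	A	T	0.3926
11	C	A	0.3926
11	C	C	1.0
11	C	G	0.3926
11	C	T	0.604
11	G	A	0.604
11	G	C	0.3926
11	G	G	1.0
11	G	T	0.3926
11	T	A	0.3926
11	T	C	0.604
11	T	G	0.3926
11	T	T	1.0
12	A	A	1.0
12	A	C	0.3692
12	A	G	0.568
12	A	T	0.3692
12	C	A	0.3692
12	C	C	1.0
12	C	G	0.3692
12	C	T	0.568
12	G	A	0.568
12	G	C	0.3692
12	G	G	1.0
12	G	T	0.3692
12	T	A	0.3692
12	T	C	0.568
12	T	G	0.3692
12	T	T	1.0
13	A	A	1.0
13	A	C	0.3458
13	A	G	0.532
13	A	T	0.3458
13	C	A	0.3458
13	C	C	1.0
13	C	G	0.3458
13	C	T	0.532
13	G	A	0.532
13	G	C	0.3458
13	G	G	1.0
13	G	T	0.3458
13	T	A	0.3458
13	T	C	0.532
13	T	G	0.3458
13	T	T	1.0
14	A	A	1.0
14	A	C	0.3224
14	A	G	0.496
14	A	T	0.3224
14	C	A	0.3224
14	C	C	1.0
14	C	G	0.3224
14	C	T	0.496
14	G	A	0.496
14	G	C	0.3224
14	G	G	1.0
14	G	T	0.3224
14	T	A	0.3224
14	T	C	0.496
14	T	G	0.3224
14	T	T	1.0
15	A	A	1.0
15	A	C	0.299
15	A	G	0.46
15	A	T	0.299
15	C	A	0.299
15	C	C	1.0
15	C	G	0.299
15	C	T	0.46
15	G	A	0.46
15	G	C	0.299
15	G	G	1.0
15	G	T	0.299
15	T	A	0.299
15	T	C	0.46
15	T	G	0.299
15	T	T	1.0
16	A	A	1.0
16	A	C	0.2756
16	A	G	0.424
16	A	T	0.2756
16	C	A	0.2756
16	C	C	1.0
16	C	G	0.2756
16	C	T	0.424
16	G	A	0.424
16	G	C	0.2756
16	G	G	1.0
16	G	T	0.2756
16	T	A	0.2756
16	T	C	0.424
16	T	G	0.2756
16	T	T	1.0
17	A	A	1.0
17	A	C	0.2522
17	A	G	0.388
17	A	T	0.2522
17	C	A	0.2522
17	C	C	1.0
17	C	G	0.2522
17	C	T	0.388
17	G	A	0.388
17	G	C	0.2522
17	G	G	1.0
17	G	T	0.2522
17	T	A	0.2522
17	T	C	0.388
17	T	G	0.2522
17	T	T	1.0
18	A	A	1.0
18	A	C	0.2288
18	A	G	0.352
18	A	T	0.2288
18	C	A	0.2288
18	C	C	1.0
18	C	G	0.2288
18	C	T	0.352
18	G	A	0.352
18	G	C	0.2288
18	G	G	1.0
18	G	T	0.2288
18	T	A	0.2288
18	T	C	0.352
18	T	G	0.2288
18	T	T	1.0
19	A	A	1.0
19	A	C	0.2054
19	A	G	0.316
19	A	T	0.2054
19	C	A	0.2054
19	C	C	1.0
19	C	G	0.2054
19	C	T	0.316
19	G	A	0.316
19	G	C	0.2054
19	G	G	1.0
19	G	T	0.2054
19	T	A	0.2054
19	T	C	0.316
19	T	G	0.2054
19	T	T	1.0
20	A	A	1.0
20	A	C	0.182
20	A	G	0.28
20	A	T	0.182
20	C	A	0.182
20	C	C	1.0
20	C	G	0.182
20	C	T	0.28
20	G	A	0.28
20	G	C	0.182
20	G	G	1.0
20	G	T	0.182
20	T	A	0.182
20	T	C	0.28
20	T	G	0.182
20	T	T	1.0
AAA	0.0
AAC	0.0
AAG	0.25
AAT	0.0
ACA	0.0
ACC	0.0
ACG	0.03
ACT	0.0
AGA	0.08
AGC	0.0
AGG	1.0
AGT	0.02
ATA	0.0
ATC	0.0
ATG	0.0
ATT	0.0
CAA	0.0
CAC	0.0
CAG	0.25
CAT	0.0
CCA	0.0
CCC	0.0
CCG	0.03
CCT	0.0
CGA	0.08
CGC	0.0
CGG	1.0
CGT	0.02
CTA	0.0
CTC	0.0
CTG	0.0
CTT	0.0
GAA	0.0
GAC	0.0
GAG	0.25
GAT	0.0
GCA	0.0
GCC	0.0
GCG	0.03
GCT	0.0
GGA	0.08
GGC	0.0
GGG	1.0
GGT	0.02
GTA	0.0
GTC	0.0
GTG	0.0
GTT	0.0
TAA	0.0
TAC	0.0
TAG	0.25
TAT	0.0
TCA	0.0
TCC	0.0
TCG	0.03
TCT	0.0
TGA	0.08
TGC	0.0
TGG	1.0
TGT	0.02
TTA	0.0
TTC	0.0
TTG	0.0
TTT	0.0
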