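chrom	arm	start	end
1	1p	1	121535434
1	1q	124535435	249250621
2	2p	1	92326171
2	2q	95326172	243199373
3	3p	1	90504854
3	3q	93504855	198022430
4	4p	1	49660117
4	4q	52660118	191154276
5	5p	1	46405641
5	5q	49405642	180915260
6	6p	1	58830166
6	6q	61830167	171115067
7	7p	1	58054331
7	7q	61054332	159138663
8	8p	1	43838887
8	8q	46838888	146364022
9	9p	1	47367679
9	9q	50367680	141213431
10	10p	1	39254935
10	10q	42254936	135534747
11	11p	1	51644205
11	11q	54644206	135006516
12	12p	1	34856694
12	12q	37856695	133851895
13	13q	19000001	115169878
14	14q	19000001	107349540
15	15q	20000001	102531392
16	16p	1	35335801
16	16q	38335802	90354753
17	17p	1	22263006
17	17q	25263007	81195210
18	18p	1	15460898
18	18q	18460899	78077248
19	19p	1	24681782
19	19q	27681783	59128983
20	20p	1	26369569
20	20q	29369570	63025520
21	21q	14288130	48129895
22	22q	19000001	51304566
X	Xp	1	58632012
X	Xq	61632013	155270560
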