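#coords=0-based-half-open
id	gene	chrom	fwd_start	fwd_end	rev_start	rev_end	pool	fwd_seq	rev_seq
GENE01_0000_001	GENE01	sim1	60	80	192	212	1	GCTCCTCACTACAGCCAGGT	ACGAGAAGGCGAGAGTGTAG
GENE02_0001_001	GENE02	sim1	272	292	407	427	1	CCCTAACCGCCTAGGCTCTC	TAATGCACACGTACTTGTTT
GENE03_0002_001	GENE03	sim1	487	507	598	618	1	TTTGCCACTCAGTTCCGACA	GTTGTCCGAGAAACGCATCA
GENE04_0003_001	GENE04	sim1	678	698	757	777	1	TTATCGCTTTTTACGGAAGG	AAGTGAACTACGTGCAGAAC
GENE05_0004_001	GENE05	sim1	837	857	951	971	1	TAAAAATGTTTACTAAGTTT	TTGGGGTAGCCATAGTGACG
GENE06_0005_001	GENE06	sim1	1031	1051	1162	1182	1	ACTGTCCGAAGGAGCGTATC	CTGGGCACTGTGGTTGCCAA
GENE07_0006_001	GENE07	sim1	1242	1262	1334	1354	1	TACATGAAGGTCTCTAAACT	TGTTGGTAGGTCCCAATCTT
GENE08_0007_001	GENE08	sim1	1414	1434	1551	1571	1	GGCTGTCTCAAGCACGCTTG	TACGTACGTAACAGCATGGA
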