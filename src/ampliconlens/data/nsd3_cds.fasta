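>NSD3_cds
ATGTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTA
CTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGA
AGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACAT
TTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTA
TTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGG
TGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGT
CCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATC
AACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTG
GTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTT
TCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTA
AACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGA
TAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTT
TATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTG
CTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGT
TACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCT
GAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAAC
ATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTG
TATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCT
GGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAAC
GTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAA
TCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTAT
TGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTC
TTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTAC
TAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAA
GATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATT
TTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTAT
TGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGT
GTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTC
CTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCA
ACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGG
TGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTT
CTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAA
ACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGAT
AATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTT
ATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGC
TCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTT
ACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTG
AAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACA
TTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGT
ATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTG
GTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACG
TCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAAT
CAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATT
GGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCT
TTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACT
AAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAG
ATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTT
TTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATT
GCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTG
TTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCC
TGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAA
CATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGT
GTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTC
TGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAA
CGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATA
ATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTA
TTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCT
CTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTA
CTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGA
AGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACAT
TTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTA
TTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAATAA
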