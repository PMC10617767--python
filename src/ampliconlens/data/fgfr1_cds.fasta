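>FGFR1_cds
ATGTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTA
CTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGA
AGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACAT
TTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTA
TTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGG
TGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGT
CCTATGGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATC
AACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTG
GTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTT
TCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTA
AACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTATGAAACGTCCTGAAGA
TAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTT
TATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTG
CTCTTTCTGGTGTTACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGT
TACTAAACGTCCTGAAGATAATCAACATTTTTATTGGTGTATTGCTCTTTCTGGTGTTACTAAACGTCCT
GAAGATAATCAACATTTTTATTGGTGTATTGCTATGTCTGGTGTTACTAAACGTCCTGAAGATAATCAAC
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
TCTTTCTGGTGTTACTTAA
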