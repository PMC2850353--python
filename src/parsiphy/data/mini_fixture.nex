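#NEXUS

BEGIN DATA;
    DIMENSIONS NTAX=8 NCHAR=84;
    FORMAT DATATYPE=MIXED(DNA:1-60,STANDARD:61-80,RESTRICTION:81-84) MISSING=? GAP=-;
    MATRIX
    T01  CTCCCAAGCCCTCCTCACGTCCTT?GAACTTGTTCATGAGACACCGTACTCCT?TAAAGC2212110100?00?1022020101
    T02  GTCT???TCCCTC?ACA?TTC?CGAGTTCCTG?TC?AACGACACGGTACTC?TCTAGAGC2201110200212(12)0112210111
    T03  TTCCCAA?GAATCTGTACGACCAGAGAACCAA?ACATAAGACATCGC?C?CTTGTAAATA(01)2010010?0112012(02)2201011
    T04  CTCTCCAGCC?GCCCTACG?CCTGGGAAC?CGTTCATATGTCATGGTACTCCTCTAGAGC221101010110201122220111
    T05  ATCCCACGGAATCCGTACGACCTG?GAACCAT?CCATAAGACACCGT?C?CTT?TAAATA10?(01)100000112012222011?1
    T06  GTCTCAAACCCTCAACA?TTCCCGAGTTCCTGGTGAAACGACACGGTACTC?TCTAGAGC221111?20021210012210111
    T07  CTCCCAATCCTTCGTTACC?CCTGAG?ACGTGGTCAAGCGGC?AAGGACTATTGTAGAGC201100010010(01)21212?00111
    T08  CTCCCAAGCCCTCC?CAAGTCCCGAGAACTTG?TCATGTGACACT?TACTCCTCTAAAGC22111?01011010(01)222120111
    ;
END;

BEGIN SETS;
    CHARSET GHR = 1-60;
    CHARSET morphology = 61-80;
    CHARSET indels = 81-84;
END;
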