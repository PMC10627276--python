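>ivt_clone chr19:45406985-45408892 hg19 IVT template transcript
UUGAGCAUUUCAUCCGGAGUCUGGCCGCCCUGACCUUCCCCCAGCCGCCUGCAGGGGGCGCCAGAGGGCC
GGAGCACGGAAAGCAGCGGAUCCUUGAUGCUGCCUUAAGUCCGGCUCAGAGGGGCGCAGCGUGGCCUGGG
GUCGCUAUCUUCCCAUCCGGAACAUCUGCCCUGCUGGGGGACACUACGGGCCUUCCCUUGCCUGAGGGUA
GGGUCUCAAGGUCACUUGCCCCCAGCUUGACCUGGCCGGAGUGGCUAUAGAGGACUUUGUCCCUGCAGAC
UGCAGCAGCAGAGAUGACACUGUCUCUGAGUGCAGAGAUGGGGGCAGGGAGCUGGGAGAGGGUUCAAGCU
ACUGGAACAGCUUCAGAACAACUAGGGUACUAGGAACUGCUGUGUCAGGGAGAAGGGGCUCAAGGACUCG
CAGGCCUGGGAGGAGGGGCCUAGGCCAGCCAUGGGAGUUGGGUCACCUGUGUCUGAGGACUUGGUGCUGU
CUGGAUUUUGCCAACCUAGGGCUGGGGUCAGCUGAUGCCCACCACGACUCCCGAGCCUCCAGGAACUGAA
ACCCUGUCUGCCCCCAGGGUCUGGGGAAGGAGGCUGCUGAGUAGAACCAACCCCAGGUUACCAACCCCAC
CUCAGCCACCCCUUGCCAGCCAAAGCAAACAGGCCCGGCCCGGCACUGGGGGUUCCUUCUCGAACCAGGA
GUUCAGCCUCCCCUGACCCGCAGAAUCUUCUGAUCCCACCCGCUCCAGGAGCCAGGAAUGAGUCCCAGUC
UCUCCCAGUUCUCACUGUGUGGUUUUGCCAUUCAUCUUGCUGCUGAACCACGGGUUUCUCCUCUGAAACA
UCUGGGAUUUAUAACAGGGCUUAGGAAAGUGACAGCGUCUGAGCGUUCACUGUGGCCUGUCCAUUGCUAG
CCCUAACAUAGGACCGCUGUGUGCCAGGGCUGUCCUCCAUGCUCAAUACACGUUAGCUUGUCACCAAACA
UACCCGUGCCGCUGCUUUCCCAGUCUGAUGAGCAAAGGAACUUGAUGCUCAGAGAGGACAAGUCAUUUGC
CCAAGGUCACACAGCUGGCAACUGGCAGAGCCAGGAUUCACGCCCUGGCAAUUUGACUCCAGAAUCCUAA
CCUUAACCCAGAAGCACGGCUUCAAGCCCCUGGAAACCACAAUACCUGUGGCAGCCAGGGGGAGGUGCUG
GAAUCUCAUUUCACAUGUGGGGAGGGGGCUCCCCUGUGCUCAAGGUCACAACCAAAGAGGAAGCUGUGAU
UAAAACCCAGGUCCCAUUUGCAAAGCCUCGACUUUUAGCAGGUGCAUCAUACUGUUCCCACCCCUCCCAU
CCCACUUCUGUCCAGCCGCCUAGCCCCACUUUCUUUUUUUUCUUUUUUUGAGACAGUCUCCCUCUUGCUG
AGGCUGGAGUGCAGUGGCGAGAUCUCGGCUCACUGUAACCUCCGCCUCCCGGGUUCAAGCGAUUCUCCUG
CCUCAGCCUCCCAAGUAGCUAGGAUUACAGGCGCCCGCCACCACGCCUGGCUAACUUUUGUAUUUUUAGU
AGAGAUGGGGUUUCACCAUGUUGGCCAGGCUGGUCUCAAACUCCUGACCUUAAGUGAUUCGCCCACUGUG
GCCUCCCAAAGUGCUGGGAUUACAGGCGUGAGCUACCGCCCCCAGCCCCUCCCAUCCCACUUCUGUCCAG
CCCCCUAGCCCUACUUUCUUUCUGGGAUCCAGGAGUCCAGAUCCCCAGCCCCCUCUCCAGAUUACAUUCA
UCCAGGCACAGGAAAGGACAGGGUCAGGAAAGGAGGACUCUGGGCGGCAGCCUCCACAUUCCCCUUCCAC
GCUUGGCCCCCAGAAUGGAGGAGGGUGUCUGGAUUACUGGGCGAGGUGUCCUCCCUUCCUGGGGACUGUG
GGGGGUGGUCAAAAGACC
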