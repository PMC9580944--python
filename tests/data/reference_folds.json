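[
 {
  "seq": "UCGCUGCUGUCGGAC",
  "structure": "((((....).)))..",
  "energy": -0.3
 },
 {
  "seq": "UCCUAGUUACGUGGC",
  "structure": "...............",
  "energy": 0.0
 },
 {
  "seq": "GUUGCUCCACAGGUA",
  "structure": "...............",
  "energy": 0.0
 },
 {
  "seq": "GCCUGCCGUCGUGGUCCGCA",
  "structure": "((..(((.....)))..)).",
  "energy": -4.5
 },
 {
  "seq": "ACACUCGCACGCUGUUUCAG",
  "structure": "....................",
  "energy": 0.0
 },
 {
  "seq": "GGCGAUCCUCCGGAUAACAC",
  "structure": "....((((...)))).....",
  "energy": -2.0
 },
 {
  "seq": "CACCUCCACAAACGAAGACAACCCU",
  "structure": ".........................",
  "energy": 0.0
 },
 {
  "seq": "CUGGUUCUUUCCCGUCCGUAAGACU",
  "structure": "..((......)).(((.....))).",
  "energy": -1.6
 },
 {
  "seq": "ACUUAUGAGGCCAUACCAGGGUCGU",
  "structure": "........((((.......))))..",
  "energy": -4.1
 },
 {
  "seq": "UUGCAAAGUCAAUAGCAGCCAUAGUCCAAC",
  "structure": "((((..........))))............",
  "energy": -1.1
 },
 {
  "seq": "UUUCCGGGUAUUGGCCGCUUGGCUAGUCGU",
  "structure": ".......(.(((((((....))))))))..",
  "energy": -7.9
 },
 {
  "seq": "CGGCACUGGCUGCUGAUACAUGCAGAGCUC",
  "structure": ".(((.(((..((......))..))).))).",
  "energy": -6.4
 },
 {
  "seq": "CUGAUAAGCUACCCGCUACGUGGCAGUCGCGCCUCCCCGA",
  "structure": ".((((..(((((.......))))).))))...........",
  "energy": -6.2
 },
 {
  "seq": "AUUAUCGGUGGUUAGCUUGUGCAGCCUUGACAUAGAAUUC",
  "structure": "....((((.((((.((....))))))))))..........",
  "energy": -7.3
 },
 {
  "seq": "CGGUGACUCGGGGACGGGCAGAGGCCGUACAUGUAUCCCG",
  "structure": "(((.((..((...((((.(...).))))...))..)))))",
  "energy": -11.3
 },
 {
  "seq": "AUGUCAGUGAUUCCAUUUUUCAUAGAGGAGUUGUUGAACUCCCAAGAAGCCCGAC",
  "structure": "......((((.........))))...((((((....)))))).............",
  "energy": -9.0
 },
 {
  "seq": "AGGAGCAGGAUUCACGGAUCGUACCGAAUAACAACUCCCUUAUUGCCGCCUACGU",
  "structure": ".((((..(......(((......))).....)..)))).................",
  "energy": -6.9
 },
 {
  "seq": "CUUCUUUAGGCGAGAGUACCCUAUUUUUGGCCCUAUGAGCGCCUUGAUGGACUCG",
  "structure": "..(((..(((((...(((.((.......))...)))...)))))....)))....",
  "energy": -10.7
 },
 {
  "seq": "UUACUUGGGACCAAUCCCAGUCGGGGUCUCUUAAAUGCCAACCACAAGAACUCUCAGGUGAAUGGUCUCA",
  "structure": ".....((((((((.((((....(((((.((((.............)))))))))..)).)).))))))))",
  "energy": -18.7
 },
 {
  "seq": "GACCGCUCGCCUACCAGACUGUCAAGCGUCACACUGUCGAAUUGUUAACGGCAGUCAUCUGCAUCGACCG",
  "structure": "(((.(.((........))).)))..(((....(((((((.........)))))))....)))........",
  "energy": -13.5
 },
 {
  "seq": "CGAUGUUGAAGAUACCCUCAAAAAUAGGUAAACUAAAGAAAUGAAUAUUUAUUCCUCUCCCAGGUAUGAU",
  "structure": "...........(((((........(((.....))).(((...((((....)))).)))....)))))...",
  "energy": -4.3
 },
 {
  "seq": "AAGGCGCUACGCUGCUCCUAAAUAAUCCGUUUGAUACUGAUUCCAUGAGGUGUAGUAGUUAGUGUAAAUGUCAAAAAGGCAAAAAAGAAC",
  "structure": "...((((((.(((((.(((....((((.((.....)).)))).....))).)))))...))))))...((((.....)))).........",
  "energy": -20.2
 },
 {
  "seq": "GGAUUAUUGGCUUAUAAUAUACCCCCAGACUAAUAUAGGUGGCUUCACGGGUUGCCAUAGUAAGUAUUGCAGACUAGGUUCGUUUUGAUC",
  "structure": "((..(((((.....)))))..))((.((.(((((((..(((((..(....)..))))).....)))))..)).)).))............",
  "energy": -11.6
 },
 {
  "seq": "GCCGGCCCUCGGCAUCAGCCUGGAUUUUACCAUGCGAGGGCCGGCCUAAAAAGGUUAGGCUUACAGGACCAACUAUGAAGACGGAAAAAG",
  "structure": "(((((((((((((....)))(((......)))...)))))))))).......((((.((((....)).))))))................",
  "energy": -31.6
 },
 {
  "seq": "ACAUUCAGACCGAAGGUGAAGCAGAUAUGCAUAUGUCGUACGAUCUUUUCAGGACACUGUAAAUGGUCCGCUAUCACACCUCGAUGGAGCCUUCCGGAAAUAUGCAAUAC",
  "structure": ".(((.....((((((((((((.((((.(((.......)))..)))))))).((((.(.......))))).(((((.......))))).))))).)))....)))......",
  "energy": -21.8
 },
 {
  "seq": "CUGCGGAGCGUCCUAGCGGAUGCGAAUCAACCAACUACGAGGGAAGAUUAUGAUCUUUAACCCAAUACUACGGAUCCCACCAAUUGUGAUUACGCUAGACAUAAACACCG",
  "structure": "(((((..((((((....)))))).......((........))((((((....))))))...((........))....(((.....)))....))).))............",
  "energy": -19.7
 },
 {
  "seq": "GUCGGCAAAUCAUUCCAAUACUGCGAAGAUCUGAUGACUUCGGAUUACCUUACACGUGGCAUAGCACUAUUAGUAGCCCAAUAGCUGCAGUAAUGGCGUGAUCUACUUGC",
  "structure": "....(((((((((.(((.((((((...(((((((.....))))))).........(((......))).......(((......))))))))).))).)))))....))))",
  "energy": -28.6
 },
 {
  "seq": "GGGGCAACGGCCCC",
  "structure": "(((((....)))))",
  "energy": -7.8
 },
 {
  "seq": "GGGACAGUACUUCCC",
  "structure": "((((......)))).",
  "energy": -4.1
 },
 {
  "seq": "GCGCGGCAUCAAAAAGAUGCCGCGC",
  "structure": "((((((((((.....))))))))))",
  "energy": -19.7
 },
 {
  "seq": "AAAAAAA",
  "structure": ".......",
  "energy": 0.0
 },
 {
  "seq": "ACGUACGUACGUACGUACGU",
  "structure": "((((((((....))))))))",
  "energy": -9.1
 }
]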