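# repgen recombination model
@structure
chain_type VDJ
factorized true
max_palindrome 2
dj_markov_direction 3to5
range del_v -2 4
range del_j -2 4
range del_d_l -2 4
range del_d_r -2 4
range ins_vj 0 40
range ins_vd 0 4
range ins_dj 0 4
forbid_dj D2:J1
gene V TVD1 - 21 0 GAAACCGCCTGGGCTACAATATGTTACAAT
gene V TVD2 - 21 0 AGACTCCATACAATACCAGGTTGTAGTTGA
gene V TVD3 - 21 0 CTGAGAGACCTGGCCTTAACCTGTCTGCTC
gene D TDD1 D1 - 0 GGGACAGGGGGC
gene D TDD2 D2 - 0 GGGACTAGCGGG
gene J TJD1 J1 9 0 TCTGTAAAGTTTATCGCG
gene J TJD2 J1 9 0 AGTGTTGTCTTTAAGCCT
gene J TJD3 J2 9 0 GTATGAACGTTTAATATC
@cpt gene_v
p 0.40121970791205264 0.32900016048788316 0.26978013160006414
@cpt gene_dj
TDD1 0.32485990416632826 0.27613091854137906 0.23471128076017217
TDD2 0.0 0.0 0.1642978965321205
@cpt del_d TDD1
-2 0.017310295066530573 0.02282038457429927 0.026608354345519707 0.02744015220309088 0.025028102498379768 0.020190353798055786 0.014405874174813876
-1 0.020867690547932596 0.027510144780954114 0.03207657075387625 0.033079309310527986 0.030171565298615432 0.024339622952224367 0.01736638937678844
0 0.02183624630985339 0.028787004296273507 0.03356537697107429 0.034614656768335014 0.031571952339482234 0.025469325446096744 0.01817243528091054
1 0.019834183839585157 0.02614765959777498 0.030487925811170942 0.03144100209098195 0.02867726888541933 0.02313416307912579 0.016506290369691423
2 0.015638154098679826 0.02061597963480317 0.024038038864632273 0.024789486660620468 0.022610436284472978 0.0182400047363343 0.013014294638311075
3 0.010702818293297391 0.01410966298050772 0.016451734678653608 0.01696602870380581 0.01547467748161669 0.012483535788814757 0.008907037867150623
4 0.006358721551646718 0.008382784386502464 0.009774247959403492 0.010079798554770175 0.009193762101778408 0.007416675298580056 0.005291818668233682
@cpt del_d TDD2
-2 0.014947800010175158 0.01948730100346294 0.021882061204113734 0.02116333990388497 0.017629514327036206 0.012649150969089806 0.007817364420714533
-1 0.018572692509739124 0.024213037981219737 0.027188535700681613 0.026295522033100954 0.021904731697587592 0.01571661323393774 0.00971310196307641
0 0.02108412093935692 0.027487162716853177 0.030865011875720025 0.02985124350810741 0.024866723659691333 0.01784183817223469 0.011026522749914667
1 0.021868416354517587 0.028509640995962343 0.032013140715078936 0.03096166179339388 0.02579172581711863 0.018505525879053027 0.011436691675752115
2 0.02072334769217979 0.02701682615515502 0.030336876479864917 0.029340454840006382 0.02444122578538267 0.01753654406433615 0.010837846426675906
3 0.017942540121342655 0.023391514461880838 0.02626605659864495 0.025403341967954154 0.021161526640529737 0.015183364683051754 0.009383546385845945
4 0.014193566852023042 0.018504014595449876 0.020777940456069073 0.020095484254097826 0.016739967754395603 0.012010902592949823 0.007422917381588511
@cpt ins_vd
len 0.3701906696496616 0.2865994689662278 0.18028070680665315 0.10467956737480974 0.058249587202647765
@cpt ins_dj
len 0.3701906696496616 0.2865994689662278 0.18028070680665315 0.10467956737480974 0.058249587202647765
@cpt markov_vd
A 0.2975909002747248 0.26381777067353374 0.2539020453274805 0.18468928372426097
C 0.2522055372126035 0.3589152554164064 0.2283802894935354 0.1604989178774547
G 0.17770316049022064 0.2690724487929929 0.29796537358065645 0.25525901713613003
T 0.28308353778017464 0.2705613915097938 0.2747444326797931 0.17161063803023827
init 0.23940097900842341 0.2623683622171489 0.24830932848242257 0.24992133029200517
@cpt markov_dj
A 0.21758317651893364 0.3668155825905541 0.1768141299629753 0.23878711092753696
C 0.07861783125768558 0.26875286296028444 0.2948923014259916 0.3577370043560383
G 0.2362385277488817 0.18765855531224343 0.34208066601454046 0.23402225092433446
T 0.22676267628414876 0.20129569437808198 0.3053506424790192 0.26659098685875005
init 0.20391202042966708 0.30381079213400763 0.3324168880837603 0.15986029935256513
@cpt del_v
TVD1 0.13373565916922903 0.15043915730180046 0.15957323333341192 0.15960415361442054 0.150526624866675 0.1338652757268346 0.11225589598762836
TVD2 0.13497983967481839 0.16302152403732967 0.1768366094154845 0.17228573324682567 0.15075674435476732 0.11848320220823232 0.08363634706254197
TVD3 0.11227265622503342 0.14359034277128033 0.1657480452437686 0.17267963585152457 0.16236886950953905 0.13779525061053569 0.10554519978831828
@cpt del_j
TJD1 0.0682644611134272 0.10387613394586032 0.1410347445461042 0.1708504567405316 0.18466383372207398 0.17808278039302153 0.1532275895389812
TJD2 0.07973351158436245 0.10616701440755065 0.13280769656108016 0.15607674137515354 0.17231874051710025 0.17873321055059288 0.17416308500416022
TJD3 0.16135421035611888 0.17477115281276265 0.17492731858773092 0.1617871247849427 0.13827052321192296 0.10919852950310811 0.07969114074341371
@error
rate 0.001
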