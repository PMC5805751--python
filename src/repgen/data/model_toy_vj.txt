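# repgen recombination model
@structure
chain_type VJ
factorized true
max_palindrome 2
dj_markov_direction 3to5
range del_v -2 4
range del_j -2 4
range del_d_l -4 16
range del_d_r -4 16
range ins_vj 0 4
range ins_vd 0 40
range ins_dj 0 40
gene V TVA - 6 0 CATGGCGTACGTTAGC
gene V TVB - 6 0 CATGGCGGTATGCAAT
gene J TJA J1 3 0 TGTTTTCGGAGCAT
gene J TJB J2 3 0 ACTTTTGGCAGCAT
@cpt gene_vj
TVA 0.4 0.2
TVB 0.25 0.15
@cpt ins_vj
len 0.3701906696496616 0.2865994689662278 0.18028070680665315 0.10467956737480974 0.058249587202647765
@cpt markov_vj
A 0.16339901958316366 0.3866229374229415 0.23681109205143747 0.21316695094245733
C 0.20187239665922782 0.3884047086113723 0.2957309890997986 0.11399190562960126
G 0.2815230918944266 0.2736403034632895 0.21500508618086628 0.22983151846141764
T 0.07811905170225561 0.30524865480098223 0.20738353248715824 0.40924876100960395
init 0.17063334121150445 0.31623615398985283 0.2958576285956345 0.21727287620300817
@cpt del_v
TVA 0.03665296867110195 0.11128674035997076 0.2167313239082244 0.2706579341214059 0.2167313239082244 0.11128674035997076 0.03665296867110195
TVB 0.03665296867110195 0.11128674035997076 0.2167313239082244 0.2706579341214059 0.2167313239082244 0.11128674035997076 0.03665296867110195
@cpt del_j
TJA 0.03665296867110195 0.11128674035997076 0.2167313239082244 0.2706579341214059 0.2167313239082244 0.11128674035997076 0.03665296867110195
TJB 0.03665296867110195 0.11128674035997076 0.2167313239082244 0.2706579341214059 0.2167313239082244 0.11128674035997076 0.03665296867110195
@error
rate 0.001
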