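casualty_id,day,triage_number,age,age_decade,gender,name_initial,triage_class
1,31,1,55,,M,K,I
2,31,5,9,,M,K,I
3,31,11,70s,,F,,I
4,31,35,80s,,M,T,III
5,31,50,30s,,,,O
6,1,75,55,,M,N,II
7,1,99,17,,M,M,I
8,1,100,28,,F,K,III
9,1,101,53,,F,K,II
10,1,123,28,,F,K,I
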