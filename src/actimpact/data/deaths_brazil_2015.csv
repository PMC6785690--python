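outcome,stratum,deaths
breast_cancer,both,
breast_cancer,men,
breast_cancer,women,10480
colon_cancer,both,5313
colon_cancer,men,2624
colon_cancer,women,2689
diabetes,both,22618
diabetes,men,11748
diabetes,women,10870
ihd,both,51566
ihd,men,34514
ihd,women,17048
stroke,both,11817
stroke,men,6917
stroke,women,4899
major_ncd,both,290874
major_ncd,men,163881
major_ncd,women,126963
all_cause,both,517134
all_cause,men,325583
all_cause,women,191477
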