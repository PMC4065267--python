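donor,receptor,result,replicates
4,3,fruit,1
3,4,no_fruit,1
3,3,no_fruit,1
4,4,no_fruit,1
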