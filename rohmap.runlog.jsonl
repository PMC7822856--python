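{"stage": "parameters", "echo": "DP=8 minpercalt=0.25 maxpercalt=0.75 binomial=1e-06 window=7 windowthres=5 maxgap=10 extend=1 minsize=1 minvar=25 minperc=88 chrX=False"}
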