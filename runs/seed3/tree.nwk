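((B10:0.237931,I03:0.237931)[100.0/100.0]:0.162488,((N15:0.197368,T29:0.197368)[100.0/100.0]:0.126919,ZH26:0.324288)[100.0/100.0]:0.0761318)[100.0/100.0];
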