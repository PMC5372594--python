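>Ex4C exendin4-cysteine (exendin-4 with C-terminal Cys)
HGEGTFTSDLSKQMEEEAVRLFIEWLKNGGPSSGAPPPSC
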