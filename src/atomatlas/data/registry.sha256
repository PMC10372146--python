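876c29f5b85d2f1e190a923e73ced96f9105431cee7dfa568459cffd329f6e7f
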