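CCO 101
CC(=O)Oc1ccccc1C(=O)O 102
c1ccc2ccccc2c1 103
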