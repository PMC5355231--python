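NSC,CELL,LCONC,GIPRCNT
101,MCF7,-8.0,98.2
101,MCF7,-7.0,91.5
101,MCF7,-6.0,64.0
101,MCF7,-5.0,21.3
101,MCF7,-4.0,-35.8
102,MCF7,-8.0,101.4
102,MCF7,-7.0,99.0
102,MCF7,-6.0,97.1
102,MCF7,-5.0,88.6
102,MCF7,-4.0,72.9
103,MCF7,-8.0,95.0
103,MCF7,-7.0,88.1
103,MCF7,-6.0,
103,MCF7,-5.0,43.7
103,MCF7,-4.0,2.1
104,A549,-6.0,55.0
104,A549,-5.0,30.2
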