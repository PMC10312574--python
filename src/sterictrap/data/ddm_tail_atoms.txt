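# DDM dodecyl tail carbons C1-C12
C1
C2
C3
C4
C5
C6
C7
C8
C9
C10
C11
C12
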