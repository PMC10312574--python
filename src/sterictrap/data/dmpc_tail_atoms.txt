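# DMPC aliphatic tail heavy atoms: chains C22-C214 and C32-C314
C22
C23
C24
C25
C26
C27
C28
C29
C210
C211
C212
C213
C214
C32
C33
C34
C35
C36
C37
C38
C39
C310
C311
C312
C313
C314
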