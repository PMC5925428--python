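>heavy_consensus VH3-framework variable-domain consensus; one residue per canonical heavy position H1..H82,H82A-C,H83..H113
EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYY
ADSVKRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAKDRGYSFDYWGQGTLVTVSS
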