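Place the four deposited assembly FASTAs here (one per file, plain text,
e.g. CP125274.fasta ... CP125277.fasta) to enable acceptance targets t1-t6.
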