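>truseq_read1_adapter
AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
>truseq_read2_adapter
AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA
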