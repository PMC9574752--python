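POLR2
PRPF8
RPL32
RPA3
RPL8
RPS19
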