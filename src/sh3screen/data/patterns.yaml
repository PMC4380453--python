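# Default SH3 target-motif grammar.
#
# Symbols: a plain residue letter is a literal; "+" = K or R; "h" (or the
# Greek phi) = the configured hydrophobic set; "x" = any residue.
classI: "+hPxxP"
classII: "PxhPx+"
PxxDY: "PxxDY"
RxAPxxP: "RxAPxxP"
RxLPxxP: "RxLPxxP"
RxIPxxP: "RxIPxxP"
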