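# Multi-token chemical name patterns, one per line; tokens space-separated,
# "*" matches any (possibly empty) character run within a token.
*yl *ate
*yl *ide
*ic acid
*ium *ide
*yl alcohol
*yl ether
*yl ester
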