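# codon:anticodon interaction-strength penalties s for tAI weights
# (dos Reis et al. 2004 selective-constraint values; overridable)
# pairing_class	s
WC	0.0
GU	0.41
IC	0.28
IA	0.9999
UG	0.68
LA	0.89
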