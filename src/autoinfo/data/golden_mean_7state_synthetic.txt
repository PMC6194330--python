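# edge-emitting hidden Markov machine
# Synthetic 7-state presentation of a golden-mean-support process with exact
# Markov order 4. States C/D, E, F, G track 1, 2, 3 and >=4 trailing zeros;
# A/B are the two "just emitted a 1" states. The probability of emitting a 1
# is q1=0.3, q2=0.7, q3=0.2, q4=0.6 for 1, 2, 3, >=4 trailing zeros, so
# histories (1,0,0,0) and (0,0,0,0) have different transition laws (order 4),
# every conditional at depth <= 4 is well separated from the mixture of the
# deeper ones, and any longer history adds nothing. No two 1s are ever
# consecutive.
# states: A B C D E F G
# n_observables: 2
# edges: source target probability symbol
A C 1.0 0
B D 1.0 0
C A 0.3 1
C E 0.7 0
D A 0.3 1
D E 0.7 0
E A 0.7 1
E F 0.3 0
F B 0.2 1
F G 0.8 0
G B 0.6 1
G G 0.4 0
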