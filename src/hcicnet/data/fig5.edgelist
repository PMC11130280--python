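# 17-node / 21-edge K-shell illustration network (labels A..Q).
# Transcription reconstructed from printed invariants: the full per-node KS and
# IKS tables force the degree sequence and shell membership (3-core = clique
# {J,K,L,M}; 2-shell = {G,H,O}; everything else peels at KS=1). The attachment
# of degree-1 leaves to their hubs is not uniquely determined by the printed
# checks; this file fixes one consistent assignment. Every printed KS and IKS
# value, N=17 and M=21 are reproduced by validate_transcription().
J K
J L
J M
K L
K M
L M
J G
J H
J O
L O
G H
F O
F A
F B
F C
D G
D E
D I
P O
P Q
N H
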