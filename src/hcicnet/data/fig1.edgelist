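# 15-node / 19-edge worked-example network (labels A..O).
# Transcription reconstructed from printed invariants: degree sequence implied
# by the published per-node tables (NCC, WNCC, tenacity T, HTGC), k_G = 6,
# a_KM = 1, a_FD = 0, and the bridging roles of C (between G and H) and
# F (between L and G). The edge set below is the unique graph consistent with
# all of those checks; validate_transcription() re-verifies them at import.
A B
A D
A G
B E
B G
C F
C G
C H
D G
E G
F G
F L
H I
H J
H K
I J
K M
K N
K O
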