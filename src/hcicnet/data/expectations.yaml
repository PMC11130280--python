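# Printed per-node values for the two worked-example networks, used by
# validate_transcription() to gate the figure transcriptions on *standard*
# quantities (NCC, K-shell, tenacity) independently of the novel metrics.
# All values at 3-decimal printed precision.
fig1:
  scalars:
    N: 15
    M: 19
    degree:
      G: 6
    edges_present:
      - [K, M]
    edges_absent:
      - [F, D]
  ncc:  # constraint coefficient, worked-example table
    A: 0.676
    B: 0.676
    C: 0.46
    D: 0.785
    E: 0.785
    F: 0.46
    G: 0.384
    H: 0.406
    I: 0.953
    J: 0.953
    K: 0.25
    L: 1.0
    M: 1.0
    N: 1.0
    O: 1.0
  wncc:  # weak-tie-weighted constraint coefficient
    A: 0.298
    B: 0.298
    C: 0.131
    D: 0.301
    E: 0.301
    F: 0.149
    G: 0.129
    H: 0.133
    I: 0.52
    J: 0.52
    K: 0.056
    L: 0.333
    M: 0.25
    N: 0.25
    O: 0.25
  tenacity:
    A: 15
    B: 15
    C: 4
    D: 15
    E: 15
    F: 7
    G: 5.5
    H: 3
    I: 15
    J: 15
    K: 3
    L: 15
    M: 15
    N: 15
    O: 15
  htgc:  # printed values divide tenacity by the 3-decimal-rounded IKS
    A: 6.175
    B: 6.175
    C: 1.647
    D: 6.562
    E: 6.562
    F: 2.882
    G: 1.925
    H: 1.167
    I: 6.562
    J: 6.562
    K: 1.667
    L: 12.5
    M: 12.5
    N: 12.5
    O: 12.5
fig5:
  scalars:
    N: 17
    M: 21
  kshell:
    A: 1
    B: 1
    C: 1
    D: 1
    E: 1
    F: 1
    G: 2
    H: 2
    I: 1
    J: 3
    K: 3
    L: 3
    M: 3
    N: 1
    O: 2
    P: 1
    Q: 1
  iks:
    A: 1.2
    B: 1.2
    C: 1.2
    D: 1.6
    E: 1.2
    F: 1.8
    G: 2.6
    H: 2.6
    I: 1.2
    J: 3.857
    K: 3.429
    L: 3.571
    M: 3.429
    N: 1.2
    O: 2.8
    P: 1.4
    Q: 1.2
# Optional external benchmark datasets (not bundled, no auto-download):
# expected node/edge counts for a user-supplied copy.
external_datasets:
  bio-DM-HT: {N: 3098, M: 4750}
  bn-fly-drosophila_medulla: {N: 1802, M: 33549}
  CL-10000-2d0-trial3: {N: 9260, M: 30173}
  p2p-Gnutella08: {N: 6301, M: 20878}
  tech-routers-rf: {N: 2154, M: 6695}
  ukerbe1: {N: 19207, M: 3522}
  Hamrle2: {N: 5952, M: 22162}
  email-enron-only: {N: 143, M: 623}
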