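# Synthetic labeled-edge graph for cut-set semantics (u, v, edge label).
# The published schematic defining cut sets is not reproduced exactly; this is
# a synthetic 6-node stand-in constructed to satisfy the printed facts:
# S1 = {c,d,f,g} disconnects the graph and no proper subset of it does
# (a minimal disconnecting set, i.e. a cut set), while removing S2 = {b,c,f}
# leaves the graph connected.
1	2	a
1	3	b
1	4	c
2	5	d
3	5	f
3	6	g
4	5	h
5	6	i
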