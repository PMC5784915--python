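# googlematrix

Google-matrix analysis of directed biological networks: PageRank/CheiRank
centralities, complex spectra, and the **reduced Google matrix** of a node
subset, whose hidden-link component infers indirect causal relations between
pathway members that are wired through the rest of the network.

## Who this is for

Systems biologists working with large directed regulatory networks —
signaling reconstructions (e.g. SIGNOR-style SIF files) merged with
cell-type-specific transcriptional layers — who want to ask: *how strongly
does protein A influence protein B once every indirect route through the
global network is taken into account, and how does that influence change
between two conditions (say, a normal and a cancer cell line)?*

## The method

For a directed network of N nodes with adjacency A (A<sub>ij</sub> = 1 when
node j points to node i), the Google matrix is

> G = α S + (1 − α)/N,  with S<sub>·j</sub> = A<sub>·j</sub>/k<sub>out</sub>(j), or uniform 1/N for dangling nodes,

where α = 0.85 is the damping factor. PageRank P is the eigenvalue-1
eigenvector of G (many/important *incoming* links → small rank index K);
CheiRank P* is the PageRank of the link-reversed network (outgoing links →
small K*); 2DRank K2 combines both.

For a subset of N<sub>r</sub> nodes of interest, write G in block form with
respect to the subset (r) and its complement, the "scattering network" (s).
The reduced Google matrix

> G<sub>R</sub> = G<sub>rr</sub> + G<sub>rs</sub> (1 − G<sub>ss</sub>)<sup>−1</sup> G<sub>sr</sub>

is the effective N<sub>r</sub> × N<sub>r</sub> column-stochastic matrix that
preserves the subset's global PageRank as its fixed point. Expanding the
resolvent around the leading eigentriple (λ<sub>c</sub>, ψ<sub>R</sub>,
ψ<sub>L</sub>) of G<sub>ss</sub> splits it exactly into

> G<sub>R</sub> = G<sub>rr</sub> + G<sub>pr</sub> + G<sub>qr</sub>,

the direct links, a near-trivial rank-one projector component, and the
**hidden-link component G<sub>qr</sub>** computed by a deflated Neumann
series. Off-diagonal entries of G<sub>qr</sub> above a threshold (0.01 by
convention) are reported as indirect interactions; comparing two conditions
classifies them as common, emergent, or disappearing.

## Worked example

Generate a 200-node background network with a planted relay
`r1 → x → r2` (x outside an 8-node subset, no direct `r1 → r2` edge), then
recover the hidden interaction:

```python
import googlematrix as gm

net, pathway, (src, dst) = gm.planted_relay(
    n_background=200, subset_size=8, relay_length=1, seed=11
)
print(f"network: {net.N} nodes, {net.n_edges} edges; subset: {len(pathway)} nodes")

model = gm.build_transition(net, alpha=0.85)
rgm = gm.compute_reduced(model, pathway.labels)
print(f"lambda_c = {rgm.lambda_c:.6f}")
print(f"weights: W_rr = {rgm.W_rr:.4f}, W_pr = {rgm.W_pr:.4f}, W_qr = {rgm.W_qr:.4f}")

hidden = gm.infer_hidden(rgm, threshold=0.01)
print(f"hidden interactions above 0.01: {len(hidden)}")
for h in hidden.interactions[:3]:
    print(f"  {h.source} -> {h.target}  G_qrnd = {h.score:.4f}")
print(f"planted pair recovered: {(src, dst) in hidden.pairs()}")
```

Output:

```
network: 201 nodes, 510 edges; subset: 8 nodes
lambda_c = 0.961217
weights: W_rr = 0.0296, W_pr = 0.9013, W_qr = 0.0691
hidden interactions above 0.01: 8
  N00118 -> N00035  G_qrnd = 0.2575
  N00185 -> N00048  G_qrnd = 0.1019
  N00039 -> N00189  G_qrnd = 0.0566
planted pair recovered: True
```

Reading: the scattering network (193 nodes) retains λ<sub>c</sub> ≈ 0.961 of
the probability flow per step, the rank-one projector part carries ~90% of
G<sub>R</sub>'s weight (it is set by the global PageRank and is structurally
trivial), and the interesting signal sits in W<sub>rr</sub> + W<sub>qr</sub>.
Eight subset pairs exceed the 0.01 hidden-interaction threshold, including
the planted relay pair.

### Command line

The same pipelines are exposed as a CLI:

```bash
googlematrix rank net.sif --out ranks.tsv
googlematrix spectrum net.sif --k 20 --out spectrum.tsv
googlematrix reduce net.sif --subset genes.txt --out reduced_out/
googlematrix compare normal.sif cancer.sif --subset genes.txt --out compare_out/
googlematrix fixtures --n 500 --seed 1 --out fixture.sif
```

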