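"""Generate self-supervised pre-training labels for a small synthetic library.

Shows the three label generators at their default rates: 15% SMILES token
masking, 85% graph-feature masking, and 15% edge corruption, plus the
pooled empirical rates over the library.
"""

from mvmol import corrupt_edges, featurize_graph, mask_graph_features, mlm_mask, tokenize_smiles
from mvmol.synthetic_data import SynthesisSpec, gen_molecules

library = gen_molecules(SynthesisSpec(n_molecules=200, seed=0))
print(f"library: {len(library)} molecules")

rec = library.records[0]
text = tokenize_smiles(rec.canonical_smiles)
plan = mlm_mask(text, seed=1)
print(f"\n{rec.canonical_smiles}")
print(f"  {len(text)} tokens, {plan.n_masked} masked at positions {sorted(plan.positions)}")

graph = featurize_graph(rec)
gplan = mask_graph_features(graph, seed=1)
eplan = corrupt_edges(graph, seed=1)
print(f"  {graph.n_tokens} graph tokens, {gplan.n_masked} feature-masked")
print(f"  {graph.n_edges} edges, {len(eplan.corrupted_edges)} rewired: "
      f"{dict(eplan.replacement_endpoints)}")

tok = [0, 0]
edge = [0, 0]
for i, r in enumerate(library.records):
    t = tokenize_smiles(r.canonical_smiles)
    tok[0] += mlm_mask(t, seed=i).n_masked
    tok[1] += len(t)
    g = featurize_graph(r)
    edge[0] += len(corrupt_edges(g, seed=i).corrupted_edges)
    edge[1] += g.n_edges
print(f"\npooled token-mask rate : {tok[0] / tok[1]:.3f}  (nominal 0.15)")
print(f"pooled edge-corrupt rate: {edge[0] / edge[1]:.3f}  (nominal 0.15)")
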