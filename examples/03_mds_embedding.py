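"""Classical MDS map of population genetic distances.

Computes pairwise FST among the provinces of the simulated national
survey and embeds the (clamped) matrix in two dimensions with Torgerson
scaling. Populations that plot close together are genetically similar;
the goodness figure is the share of positive-eigenvalue variance the two
axes capture.
"""

from ystrkit import DistanceModel, classical_mds, make_fixture, pairwise_fst_matrix

ds, _ = make_fixture("tiny")
fst = pairwise_fst_matrix(ds, DistanceModel.identity, B=499, seed=3)
emb = classical_mds(fst.clamped(), m=2)

print("MDS coordinates (dim1/dim2):")
print(emb.coordinates.round(4).to_string())
print(f"\ngoodness of fit: {emb.goodness:.3f} "
      "(1.0 = the plane reproduces the FST matrix exactly)")
print("eigenvalues:", [round(float(v), 5) for v in emb.eigenvalues])
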