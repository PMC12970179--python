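"""Drug-target interaction: sixfold cross-validated affinity recovery.

Synthetic affinities are a noisy bilinear map of protein latent factors and
ligand descriptors.  The DTI head (64-D ligand + 64-D protein projections
concatenated to 128-D) is trained per fold with staged unfreezing; per-fold
and mean Pearson r / RMSE are printed.
"""

from mvmol.dti import crossval_dti
from mvmol.synthetic_data import _descriptor_vector, gen_dti_dataset

pairs, proteins = gen_dti_dataset(
    n_ligands=40, n_proteins=15, protein_dim=32, latent_rank=4, noise_sd=0.1, seed=0
)
print(f"{len(pairs)} ligand-protein pairs, {len(proteins)} proteins")

result = crossval_dti(pairs, proteins, _descriptor_vector, seed=0)
for f in result.folds:
    print(f"  fold {f.fold}: r={f.pearson_r:.3f}  rmse={f.rmse:.3f}  (n={f.n_test})")
print(f"mean: r={result.mean_pearson_r:.3f}  rmse={result.mean_rmse:.3f}")
# r near 1 shows the head recovers the planted bilinear structure; every
# pair appears in exactly one test fold
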