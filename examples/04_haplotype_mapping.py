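"""Map the fertility/milk QTL with ancestral-haplotype mixed models.

Clusters phased haplotypes around the deletion into ancestral states with a
hidden Markov model, finds the state tagging the deletion, and fits the
weighted variance-component model to fertility-index and milk proofs. The
tag state shows the antagonistic effect pattern (fertility down, milk up)
that keeps the deletion segregating; conditioning on its dosage removes the
QTL signal.
"""

import numpy as np

from lethalmap import assoc, cnvcall, simpop

cfg = simpop.PopulationConfig(
    breeds=[simpop.BreedConfig("RED", 60, 240, 300, 0.128)],
    n_generations=1, n_markers_50k=300, n_markers_in_deletion_50k=3,
    n_markers_hd=0, n_markers_in_deletion_hd=0)
cohort = simpop.simulate_population(cfg, seed=4)
traits = simpop.simulate_trait_proofs(cohort, cfg.traits, seed=5)

d = cohort.deletion
pos = cohort.markers.positions
centre = (d.start_bp + d.end_bp) // 2
win = (pos >= centre - 4_000_000) & (pos <= centre + 4_000_000)
haps = cohort.phased.haplotypes[:, :, win].reshape(-1, int(win.sum()))
owners = np.repeat(np.arange(cohort.phased.n_animals), 2)
# K comfortably above the simulator's ancestral-pool size so the
# deletion background gets its own state
model = assoc.fit_ancestral_hmm(haps, pos[win], K=15, n_starts=2, seed=6,
                                n_iter=20, hap_owner=owners)

j = int(np.searchsorted(pos[win], centre))
in_del = np.where((pos[win] >= d.start_bp) & (pos[win] <= d.end_bp))[0]
post = model.posterior_mean(in_del if len(in_del) else [j])
flags = cohort.phased.del_flags.reshape(-1)
tag = int(np.bincount(post.argmax(axis=1)[flags],
                      minlength=model.n_states).argmax())
ld = cnvcall.ld_r2(flags.astype(int), (post.argmax(axis=1) == tag).astype(int))
print(f"ancestral state {tag} tags the deletion: LD r2 = {ld.r2:.3f}")

D = model.state_dosages(j, cohort.phased.n_animals)
kin = assoc.kinship_matrix(cohort.pedigree)
for trait in ("fertility_index", "milk"):
    tt = traits.trait(trait).set_index("animal_id").loc[cohort.phased.animal_ids]
    w = assoc.reliability_weights(tt["reliability"].to_numpy())
    fit = assoc.haplotype_lrt(tt["value"].to_numpy(), D, None, kin, w)
    print(f"{trait}: LRT = {fit.statistic:.1f} (p = {fit.p_value:.2e}), "
          f"tag-state effect {fit.state_effects[tag]:+.2f} genetic SD")

tt = traits.trait("fertility_index").set_index("animal_id") \
    .loc[cohort.phased.animal_ids]
w = assoc.reliability_weights(tt["reliability"].to_numpy())
cond = assoc.haplotype_lrt(tt["value"].to_numpy(),
                           np.delete(D, tag, axis=1), D[:, [tag]], kin, w)
print(f"after conditioning on the tag state: p = {cond.p_value:.3f} "
      "(signal annihilated)")
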