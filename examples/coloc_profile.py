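"""The co-localization score Q and its relationship with ECC.

Q for an interacting pair is the Jaccard overlap of their experimental
location sets.  Binning edges by ECC and averaging Q per bin shows that the
more densely embedded an interaction, the likelier its endpoints share
compartments — the observation that justifies ECC-weighted neighbor voting.
"""

from netloc import colocalization_score, profile
from netloc.simulate import SimulationConfig, simulate_dataset

print("Q({Nucleus}, {Nucleus}) =", colocalization_score({"Nucleus"}, {"Nucleus"}))
print("Q({Nucleus}, {ER})      =", colocalization_score({"Nucleus"}, {"ER"}))
print("Q({Nucleus,Cytoplasm}, {Nucleus}) =",
      colocalization_score({"Nucleus", "Cytoplasm"}, {"Nucleus"}))

config = SimulationConfig(n_proteins=400, n_communities=8, p_within=0.3,
                          p_between=0.015, annotation_coverage=0.8, seed=1)
sim_net, ann = simulate_dataset(config)
prof = profile(sim_net.network, ann.scl, n_bins=10)

print(f"\n{prof.n_edges} doubly annotated edges in 10 ECC bins:")
print("   bin          n   mean ECC   mean Q")
for b in prof.bins:
    if b.n:
        print(f"  [{b.lo:.1f},{b.hi:.1f})  {b.n:5d}    {b.mean_ecc:.3f}    "
              f"{b.mean_q:.3f}")
print(f"linear fit through the bin means: slope {prof.slope:.2f}, "
      f"Pearson r {prof.r:.2f}")
# A clearly positive slope/r: high-ECC interactions co-localize more.
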