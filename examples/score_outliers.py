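"""Score a synthetic cohort for one phenotype term and find the outlier.

Builds a small world with one planted single-rare-variant outlier, scores
the planted term against a 300-genome background, and prints the top of
the transformed score ranking.
"""

import numpy as np

from genofirst import score_term
from genofirst.simulate import PlantSpec, SimulationConfig, generate_world

config = SimulationConfig(
    seed=7,
    n_background=300,
    n_subjects=10,
    n_terms=60,
    n_domains=20,
    plants=(PlantSpec("single_rare"),),
)
world = generate_world(config)
(truth,) = world.truth
print(f"planted outlier: {truth.subject} on term {truth.term} "
      f"via {truth.variant_ids[0]}")

profile = world.build_profile(truth.term)
print(f"term profile: {profile.n_sites} missense sites in domains linked "
      f"to {truth.term}")

scores = score_term(
    profile, world.profile_genotypes(profile), world.individuals, seed=7
)
order = np.argsort(scores.transformed)[::-1]
print(f"\nhidden structure: {scores.has_structure} (k={scores.k})")
print("top 5 transformed scores (0-1 scale, comparable across terms):")
for i in order[:5]:
    print(f"  {scores.individuals[i]:>9}  raw={scores.raw[i]:7.2f}  "
          f"transformed={scores.transformed[i]:.4f}")
print("\nThe planted subject should top the ranking: its homozygous rare "
      "allele at a\nstrongly conserved domain position makes it the "
      "genetic extreme for this term.")
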