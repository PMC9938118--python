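"""Confirm genetics-first predictions against questionnaire answers.

Runs the full pipeline on a small world with planted outliers: scores
every term, builds decoy-mixed questionnaires for the subjects, simulates
self-reported answers (planted predictions answered yes at 90%, everything
else at the 0.8% background rate) and applies the permutation tests.
"""

from genofirst.io import RunConfig
from genofirst.pipeline import run_pipeline
from genofirst.simulate import PlantSpec, SimulationConfig, generate_world

world = generate_world(
    SimulationConfig(
        seed=13,
        n_background=80,
        n_subjects=4,
        n_terms=30,
        n_domains=10,
        plants=(PlantSpec("single_rare"), PlantSpec("combinatorial")),
    )
)
config = RunConfig(seed=13, n_perm=2000, n_top=10)
result = run_pipeline(world, config)

print(f"{len(result.scores)} terms scored, {len(result.calls)} calls")
for call in result.calls:
    planted = any(
        t.subject == call.individual_id and t.term == call.term_id
        for t in world.truth
    )
    print(f"  {call.individual_id} x {call.term_id}: score="
          f"{call.transformed_score:.3f} type={call.outlier_type}"
          f"{'  <- planted' if planted else ''}")

print(f"\nanswer records: {len(result.answers)}; "
      f"yes answers: {int(result.answers['answer'].sum())}")
g = result.global_test
print(f"global permutation test: mean yes-score={g.observed:.4f} "
      f"p={g.p_value:.4g} z={g.z_score:.2f}")
print("\nA small p-value says yes-answers land on higher outlier scores "
      "than random\nre-allocation would give - the predictions carry signal.")
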