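"""Graph-aware closeness of ontology terms for automated confirmation.

Builds a four-term branch (a finger-deviation-style nest of terms), derives
information content from cumulative patient counts, and shows which pairs
count as close matches within the default band of 1 nat.
"""

import itertools

import networkx as nx

from genofirst.term_profiles import (
    Ontology,
    close_match,
    cumulative_annotation_counts,
    information_content,
)

g = nx.DiGraph()
terms = {
    "T:root": "phenotypic abnormality",
    "T:hand": "deviation of the hand or of fingers",
    "T:finger": "deviation of finger",
    "T:fifth": "deviation of the 5th finger",
}
for t, name in terms.items():
    g.add_node(t, name=name)
g.add_edge("T:hand", "T:root")
g.add_edge("T:finger", "T:hand")
g.add_edge("T:fifth", "T:finger")
onto = Ontology(g)

# patients annotated at each level; counts accumulate up the graph
annotations = {f"p{i}": ["T:fifth"] for i in range(56)}
annotations.update({f"q{i}": ["T:finger"] for i in range(2)})
annotations.update({f"r{i}": ["T:hand"] for i in range(1)})
annotations.update({f"s{i}": ["T:root"] for i in range(1074)})
counts = cumulative_annotation_counts(annotations, onto)
total = len(annotations)

print("term                      count   IC (nats)")
for t in ["T:root", "T:hand", "T:finger", "T:fifth"]:
    ic = information_content(t, counts, total)
    print(f"{terms[t]:<25} {counts[t]:>5}   {ic:.3f}")

print("\nclose matches (ancestor/descendant and |delta IC| <= 1 nat):")
for a, b in itertools.combinations(terms, 2):
    if close_match(a, b, onto, counts, total, delta_ic=1.0):
        print(f"  {terms[a]}  <->  {terms[b]}")
print("\nNested terms annotating similar patient sets match; the root, "
      "annotating\nnearly everyone, is too uninformative to match anything.")
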