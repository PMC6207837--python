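"""Ask the part-of ontology which anchors it licenses for an NSS term.

The ontology is a soft constraint: `may_be_part_of(part, whole)` answers
"could a structure named *part* plausibly be a part of *whole*?" using
part_of edges expanded through subclass closure.  Compound names absent from
the ontology fall back to their head word, and self-parthood is always
rejected.
"""

from nssresolve import may_be_part_of, ontology_from_edges

onto = ontology_from_edges(
    part_of=[("elytron side", "elytron"), ("leaf apex", "leaf")],
    subclass_of=[("elytron side", "side"), ("leaf apex", "apex")],
)

queries = [
    ("side", "elytron"),   # licensed via the subclass-encoded compound
    ("apex", "leaf"),      # same pattern for a plant organ
    ("apex", "elytron"),   # never stated -> rejected
    ("upper side", "elytron"),  # compound absent; head word "side" licenses it
    ("side", "side"),      # self-parthood is always False
]
for part, whole in queries:
    verdict = may_be_part_of(onto, part, whole)
    print(f"may_be_part_of({part!r}, {whole!r}) = {verdict}")

print()
print("Because licensing is single-hop by default, the resolver only accepts")
print("candidate anchors the ontology explicitly (or via subclasses) supports.")
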