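"""Resolve the two walk-through statements with the syntactic rule cascade.

The first statement is a real sentence from a fern description in which six
non-specific structure (NSS) terms — edges, adaxial side, lower surface,
surfaces, cells, long axes — must each be linked to an anchor organ.  The
second is a one-line beetle-style statement whose NSS term *edge* is anchored
to another NSS term (*upper margin*), exercising recursive resolution and
compound anchor naming.
"""

from nssresolve import resolve_statement, worked_examples

statements, ontology, lexicon = worked_examples()

for statement in statements:
    print(f"--- {statement.id}")
    print(" ".join(t.text for t in statement.tokens))
    for resolution in resolve_statement(statement, ontology):
        nss = statement.entity(resolution.nss_mention)
        print(
            f"  {nss.name!r:18} -> {resolution.anchor_name!r:24}"
            f" (rule: {resolution.rule_fired})"
        )
    print()

print("The chained case shows why recursion matters: 'edge' anchors to the")
print("NSS 'upper margin', which itself anchors to 'abdomen', so the final")
print("compound name reads outermost organ first: 'abdomen upper margin'.")
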