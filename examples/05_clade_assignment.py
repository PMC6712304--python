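"""Assign molecules to phylogenetic clades.

A molecule positively associated with several related microbes is assigned
to the minimal clade containing at least 80% of those microbes — provided
that clade is a proper subtree of the pruned phylogeny.
"""

from assocnet import AssociationEdge, assign_all, load_tree

tree = load_tree("(((otu1,otu2),(otu3,otu4)),((otu5,otu6),otu7));", is_path=False)


def edge(mol, mic, sign="positive"):
    return AssociationEdge(molecule_id=mol, microbe_id=mic, test="fisher",
                           statistic=2.0, p_value=1e-15, sign=sign)


edges = [
    # molA sits on the (otu1, otu2) cherry
    edge("molA", "otu1"), edge("molA", "otu2"),
    # molB covers a 4-leaf clade
    edge("molB", "otu1"), edge("molB", "otu2"), edge("molB", "otu3"),
    edge("molB", "otu4"),
    # molC spans both sides of the root: no proper clade reaches 80%
    edge("molC", "otu1"), edge("molC", "otu5"),
    # negative associations carry no production/biotransformation evidence
    edge("molA", "otu7", sign="negative"),
    edge("molD", "otu6"),
]

for a in assign_all(tree, edges, percent=80):
    print(f"{a.molecule_id}: clade {a.clade_label} "
          f"({a.n_marked_in_clade}/{a.n_marked_total} marked microbes, "
          f"{a.n_leaves_in_clade} leaves, coverage {a.fraction:.0%})")
print("\nmolC is absent: its positive partners straddle the root, so only "
      "the whole tree would cover them")
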