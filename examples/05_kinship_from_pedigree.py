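"""Build the additive relatedness matrix A from a pedigree.

A three-generation toy pedigree: the printed matrix shows the classical
values (parent-offspring and full-sib A = 0.5, grandparent-grandchild
A = 0.25) and a diagonal above 1 for the inbred individual.
"""

from behavstate import Pedigree, kinship_matrix, relatedness_matrix

ped = Pedigree(
    (
        ("gp1", "", ""),
        ("gp2", "", ""),
        ("s1", "gp1", "gp2"),
        ("s2", "gp1", "gp2"),
        ("mate", "", ""),
        ("child", "s1", "mate"),
        ("inbred", "s1", "s2"),  # full-sib mating
    )
)
A = relatedness_matrix(kinship_matrix(ped))
print(A.to_dataframe().round(3).to_string())
print("\nfull sibs s1-s2:", A.to_dataframe().loc["s1", "s2"])
print("grandchild gp1-child:", A.to_dataframe().loc["gp1", "child"])
print("inbred diagonal:", A.to_dataframe().loc["inbred", "inbred"])
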