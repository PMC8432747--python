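"""Build a small three-generation pedigree, compute kinship, classify pairs.

The relationship matrix printed is the expected additive relationship 2*phi:
1 on the diagonal (non-inbred), 0.5 for parent-offspring and full sibs,
0.25 for grandparent-grandchild and avuncular pairs.
"""

import pandas as pd

from famvc import classify_relationships, kinship_matrix, pedigree_from_frame

ped = pedigree_from_frame(pd.DataFrame({
    "id":     ["gf", "gm", "dad", "mom", "kid1", "kid2", "uncle"],
    "father": [None, None, "gf", None, "dad", "dad", "gf"],
    "mother": [None, None, "gm", None, "mom", "mom", "gm"],
    "sex":    ["male", "female", "male", "female", "male", "female", "male"],
    "family": ["F1"] * 7,
}))

kin = kinship_matrix(ped)
print("2*phi matrix:")
print(pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids).round(3))

print("\nrelated pairs per class:")
print(classify_relationships(ped).to_string())
# grandparent-grandchild and avuncular share 2*phi = 0.25 but are separated
# by their pedigree paths.
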