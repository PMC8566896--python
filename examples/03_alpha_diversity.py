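"""Alpha diversity of a toy OTU table with a phylogeny.

Five OTUs on a unit-branch star tree, two samples: the suite reports
observed OTUs, bias-corrected Chao1, Shannon (nats), Gini-Simpson,
Pielou and Faith's phylogenetic diversity.
"""

import io

import pandas as pd
from skbio import TreeNode

from domchemodiv import OTUTable, alpha_diversity_table

counts = pd.DataFrame(
    {"young_soil": [1, 1, 1, 1, 12], "old_soil": [5, 5, 5, 5, 5]},
    index=["A", "B", "C", "D", "E"],
)
tree = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1,E:1);"))
table = OTUTable(counts=counts, tree=tree)

print(alpha_diversity_table(table).round(4).to_string())
print("\nChao1 exceeds observed richness in young_soil because its four")
print("singletons suggest unseen OTUs; old_soil's even counts give maximal")
print("Pielou evenness; Faith's PD is the branch length spanning observed tips.")
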