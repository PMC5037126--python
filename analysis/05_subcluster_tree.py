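#!/usr/bin/env python
"""Distance-based companion tree for one subfamily cluster.

Takes the members of one planted subfamily (default fam1-sub1) plus the
representatives of its sibling subfamilies as outgroups, computes
corrected distances from pairwise local-alignment identities, and builds
a neighbor-joining tree (results/subcluster.nwk).  This is an
approximation: no multiple alignment, no bootstrap.
"""

import argparse
from pathlib import Path

from desatnet.phylo import distance_matrix, neighbor_joining, write_newick
from desatnet.synth import SynthConfig, generate

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--subfamily", default="fam1-sub1")
parser.add_argument("--n-members", type=int, default=10)
parser.add_argument("--out", type=Path, default=Path("results/subcluster.nwk"))
args = parser.parse_args()

records, truth = generate(SynthConfig(seed=args.seed))
members = [
    r for r in records if truth.subfamily.get(r.id) == args.subfamily
][: args.n_members]
family = args.subfamily.split("-")[0]
outgroups = []
seen = set()
for r in records:
    sub = truth.subfamily.get(r.id, "")
    if truth.family.get(r.id) == family and sub != args.subfamily and sub not in seen:
        outgroups.append(r)
        seen.add(sub)

taxa = members + outgroups
dm = distance_matrix(taxa)
tree = neighbor_joining(dm)
write_newick(tree, args.out)
print(f"{len(members)} members of {args.subfamily} + "
      f"{len(outgroups)} sibling-subfamily outgroups")
print(f"tree ({tree.n_edges()} edges, "
      f"{tree.n_negative_clamped} clamped branches) -> {args.out}")
print(tree.to_newick())
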