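"""Pleiotropy and precursor contributions on a branched biomass.

A shared upstream enzyme (g0) feeds three biomass precursors produced by
branch enzymes b1..b3.  Pleiotropy counts the precursors whose maximal
producibility a 90% knockdown limits; xi measures how much of each
precursor's biomass demand a gene set's reactions produce.
"""

import metapgs as mp
from metapgs.fba import pfba
from metapgs.mutations import apply_dosages

sc = mp.toy_branched(n_precursors=3, shared_upstream=True, slack_upstream=1.0)
G, _ = mp.scenario_dataset(sc, 6, sigma=0.1, seed=3)

pleio = mp.pleiotropy(sc.network, sc.ref, G, sc.medium)
print("pleiotropy (mean over individuals):")
print(pleio.mean.round(2).to_string())
print("-> the shared enzyme limits all 3 precursors, each branch only its own\n")

sols = [pfba(apply_dosages(sc.network, sc.ref, G.row(i)), sc.medium) for i in range(len(G))]
xi = mp.precursor_contribution(sc.network, sols, ["b1"], n_randomizations=1000, seed=0)
print("xi of the set {b1} (% of each precursor's biomass demand produced):")
print(xi.round(3).to_string())
print("\nb1 produces 100% of precursor p1 consumed by growth and none of the "
      "others; the p-value compares against size-matched random gene sets.")
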