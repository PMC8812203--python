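"""Dataset statistics for the four classic DTI benchmark shapes.

Builds synthetic networks with the published drug/target/interaction
counts of the nuclear-receptor, enzyme, GPCR and ion-channel benchmarks
and prints their sparsity. Sparsity depends only on the counts, not on
where the edges sit, so these numbers match the published tables.
"""

from csln.network import summarize
from csln.synthetic import network_with_counts

SHAPES = {
    "nuclear receptor": (54, 26, 90),
    "enzyme": (445, 664, 2926),
    "GPCR": (223, 95, 635),
    "ion channel": (210, 204, 1476),
}

print(f"{'dataset':<18}{'drugs':>7}{'targets':>9}{'edges':>7}{'sparsity %':>12}")
for name, (n_drugs, n_targets, n_inter) in SHAPES.items():
    net, _ = network_with_counts(n_drugs, n_targets, n_inter, seed=0)
    s = summarize(net)
    print(
        f"{name:<18}{s.n_drugs:>7}{s.n_targets:>9}"
        f"{s.n_interactions:>7}{s.sparsity_display:>12.2f}"
    )

# A sparsity above ~94% means fewer than 1 in 16 drug-target pairs is a
# known interaction -- the regime cold-start screening has to work in.
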