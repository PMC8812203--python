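"""MACCS fingerprints and Tanimoto similarity from SMILES (needs RDKit).

Fingerprints ten common small molecules and prints the most and least
similar pairs. Tanimoto = |shared bits| / |union of bits|.
"""

from itertools import combinations

from csln.chem import fingerprint_from_smiles, tanimoto

MOLECULES = {
    "ethanol": "CCO",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "caffeine": "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "urea": "NC(=O)N",
}

fps = {name: fingerprint_from_smiles(smi, name) for name, smi in MOLECULES.items()}
for name, fp in fps.items():
    print(f"{name:<12} {fp.n_set:>3} set bits")

pairs = sorted(
    ((tanimoto(fps[a], fps[b]), a, b) for a, b in combinations(fps, 2)),
    reverse=True,
)
print("\nmost similar:", f"{pairs[0][1]} / {pairs[0][2]}  TN={pairs[0][0]:.3f}")
print("least similar:", f"{pairs[-1][1]} / {pairs[-1][2]}  TN={pairs[-1][0]:.3f}")
# Structurally related analgesics score far higher than unrelated pairs,
# which is the signal the screening method exploits.
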