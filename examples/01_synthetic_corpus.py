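"""Generate a labeled synthetic peptide corpus with toy structures.

Builds 50 variable-length peptides with a hemolysis-like 15/85 class
imbalance, writes FASTA + labels CSV + one ideal-helix PDB per peptide,
and prints the class composition.
"""

from pathlib import Path

import pepclip as pc

out = Path("scratch_example_corpus")
spec = pc.FixtureSpec(
    n_peptides=50, length_range=(5, 30), positive_fraction=0.15, seed=1
)
manifest = pc.generate_corpus(spec, out)

records = [
    pc.LabeledSequence(pid, e["sequence"], e["label"])
    for pid, e in manifest["peptides"].items()
]
pos_pct, neg_pct = pc.class_fraction(records)
print(f"wrote {len(records)} peptides to {out}/")
print(f"class composition: {pos_pct}% positive / {neg_pct}% negative")
# positives are peptides whose hydrophobic-residue fraction exceeds 1/2;
# the percentages mirror the imbalance of real hemolysis corpora.

example = records[0]
atoms = pc.parse_pdb((out / manifest["peptides"][example.id]["pdb"]).read_text())
print(f"{example.id}: {len(example.sequence)} residues -> {len(atoms)} atoms "
      f"(4 backbone per residue + CB for non-glycine)")
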