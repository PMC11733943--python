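"""Synthetic peptide corpora and toy structures.

Every downstream stage is testable offline: labeled variable-length
peptides are drawn over the canonical 20-letter alphabet with a
configurable class imbalance, and each sequence gets a geometrically
valid ideal α-helix structure written as standard PDB text.

The default label rule is deterministic in the sequence (hydrophobic
residue fraction above one half), so both the sequence view and the
structure view — which is itself derived from the sequence — carry a
learnable signal.  Positive and negative draws use class-conditional
residue compositions (hydrophobic-rich vs hydrophobic-poor), emulating
the real separation between hemolytic and benign peptides rather than
piling every example onto the decision boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codec import ALPHABET, validate_sequence
from .prep import LabeledSequence, write_labels_csv

__all__ = [
    "FixtureSpec",
    "LABEL_RULES",
    "hydrophobic_fraction_rule",
    "generate_peptides",
    "generate_structure",
    "generate_corpus",
]

HYDROPHOBIC = set("AFILMVWY")

# ideal α-helix parameterization: 1.5 Å rise and 100° rotation per residue
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
CA_RADIUS = 2.3

# (radius, angular offset in degrees, z offset) per backbone atom family
_ATOM_GEOMETRY = {
    "N": (1.6, -28.0, -0.9),
    "CA": (CA_RADIUS, 0.0, 0.0),
    "C": (2.0, 28.0, 0.7),
    "O": (2.6, 33.0, 1.1),
    "CB": (3.4, 0.0, 0.5),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def hydrophobic_fraction_rule(sequence: str) -> int:
    """Positive iff more than half the residues are hydrophobic."""
    frac = sum(ch in HYDROPHOBIC for ch in sequence) / len(sequence)
    return int(frac > 0.5)


LABEL_RULES = {"hydrophobic_fraction": hydrophobic_fraction_rule}


@dataclass(frozen=True)
class FixtureSpec:
    n_peptides: int
    length_range: tuple[int, int] = (1, 190)
    positive_fraction: float = 0.15065
    label_rule: str = "hydrophobic_fraction"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie strictly in (0, 1)")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be at least 1")
        if self.label_rule not in LABEL_RULES:
            raise ValueError(f"unknown label rule {self.label_rule!r}")


def n_positive_for(spec: FixtureSpec) -> int:
    """Positive-record count: floor(n * fraction + 0.5)."""
    return int(np.floor(spec.n_peptides * spec.positive_fraction + 0.5))


def _draw_sequence(rng: np.random.Generator, length: int, p_hydro: float) -> str:
    hydro = sorted(HYDROPHOBIC)
    other = sorted(set(ALPHABET) - HYDROPHOBIC)
    picks = rng.random(length) < p_hydro
    return "".join(
        hydro[rng.integers(len(hydro))] if h else other[rng.integers(len(other))]
        for h in picks
    )


def generate_peptides(spec: FixtureSpec) -> list[LabeledSequence]:
    """Draw a labeled corpus meeting the requested class balance.

    Target-class draws use hydrophobic-residue probability 0.7 (positive)
    or 0.3 (negative); every draw is re-checked against the pure label
    rule and rejected on mismatch, so labels remain a function of the
    sequence alone.
    """
    rule = LABEL_RULES[spec.label_rule]
    rng = np.random.default_rng(spec.seed)
    n_pos = n_positive_for(spec)
    targets = [1] * n_pos + [0] * (spec.n_peptides - n_pos)
    lo, hi = spec.length_range
    records: list[LabeledSequence] = []
    for i, want in enumerate(targets):
        for attempt in range(1000):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, 0.7 if want else 0.3)
            if rule(seq) == want:
                break
        else:
            raise ValueError(
                f"length_range {spec.length_range} infeasible for label rule "
                f"{spec.label_rule!r} (class {want} unreachable in 1000 draws)"
            )
        records.append(LabeledSequence(id=f"pep{i:05d}", sequence=seq, label=want))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def _pdb_atom_line(serial, name, res3, resseq, xyz, bfactor, element):
    pad_name = f" {name:<3}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5} {pad_name} {res3:>3} A{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bfactor:6.2f}          {element:>2}"
    )


def generate_structure(sequence: str, seed: int = 0) -> str:
    """Render a sequence as an ideal α-helix in PDB text.

    Backbone atoms N, CA, C, O per residue plus a CB pseudo side-chain
    atom for every non-glycine residue; the B-factor column carries a
    synthetic per-atom confidence drawn uniformly from [50, 95] so that
    confidence-based selection logic sees values on both sides of the
    conventional 70 threshold.
    """
    validate_sequence(sequence)
    rng = np.random.default_rng(seed)
    lines = ["MODEL        1"]
    serial = 0
    for i, aa in enumerate(sequence):
        theta0 = np.deg2rad(HELIX_TWIST_DEG * i)
        z0 = HELIX_RISE * i
        names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
        for name in names:
            radius, dphi, dz = _ATOM_GEOMETRY[name]
            phi = theta0 + np.deg2rad(dphi)
            xyz = (radius * np.cos(phi), radius * np.sin(phi), z0 + dz)
            serial += 1
            conf = 50.0 + 45.0 * rng.random()
            lines.append(
                _pdb_atom_line(
                    serial, name, _ONE_TO_THREE[aa], i + 1, xyz, conf, _ELEMENT_OF[name]
                )
            )
    lines += ["ENDMDL", "END", ""]
    return "\n".join(lines)


def expected_atom_count(sequence: str) -> int:
    """4 backbone atoms per residue plus one CB per non-glycine residue."""
    g = sequence.count("G")
    return 4 * len(sequence) + (len(sequence) - g)


def generate_corpus(spec: FixtureSpec, out_dir) -> dict:
    """Write a full corpus: FASTA, labels CSV, one PDB per peptide, and a
    manifest mapping id to files (with content checksums)."""
    out = Path(out_dir)
    pdb_dir = out / "pdbs"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    records = generate_peptides(spec)

    fasta_path = out / "sequences.fasta"
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")

    entries = {}
    for i, r in enumerate(records):
        struct_seed = (spec.seed * 100003 + i) % (2**31 - 1)
        pdb_text = generate_structure(r.sequence, seed=struct_seed)
        pdb_path = pdb_dir / f"{r.id}.pdb"
        pdb_path.write_text(pdb_text)
        entries[r.id] = {
            "sequence": r.sequence,
            "label": r.label,
            "pdb": str(pdb_path.relative_to(out)),
            "pdb_sha256": hashlib.sha256(pdb_text.encode()).hexdigest(),
        }

    labeled = [
        LabeledSequence(r.id, r.sequence, r.label, structure_ref=entries[r.id]["pdb"])
        for r in records
    ]
    labels_path = out / "labels.csv"
    write_labels_csv(labeled, labels_path)

    manifest = {
        "spec": {
            "n_peptides": spec.n_peptides,
            "length_range": list(spec.length_range),
            "positive_fraction": spec.positive_fraction,
            "label_rule": spec.label_rule,
            "seed": spec.seed,
        },
        "fasta": fasta_path.name,
        "labels": labels_path.name,
        "fasta_sha256": hashlib.sha256(fasta_path.read_bytes()).hexdigest(),
        "peptides": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
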