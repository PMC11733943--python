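"""PDB parsing, confidence-based model selection, atom featurization and
radius-graph construction.

The node feature table carries, per atom: coordinates (x, y, z in Å),
atomic number, standard atomic mass (u), covalent radius (Å), a
side-chain indicator, a 0-based residue ordinal, the atom count of the
owning residue, and the residue sequence number as printed in the PDB.
AlphaFold-style files store a per-atom confidence (pLDDT) in the
B-factor column; it is read into ``AtomRecord.confidence`` and drives
best-model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AtomRecord",
    "PeptideGraph",
    "BACKBONE_ATOMS",
    "parse_pdb",
    "select_best_model",
    "featurize_atoms",
    "build_graph",
    "element_table",
    "graph_from_pdb",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

FEATURE_COLUMNS = [
    "x",
    "y",
    "z",
    "atomic_number",
    "atomic_mass",
    "atomic_radius",
    "is_sidechain",
    "residue_index",
    "atoms_in_residue",
    "residue_seq_number",
]


def element_table() -> dict[str, dict]:
    text = resources.files("pepclip.data").joinpath("elements.json").read_text()
    table = json.loads(text)
    table.pop("_comment", None)
    return table


_ELEMENTS = None


def _elements() -> dict[str, dict]:
    global _ELEMENTS
    if _ELEMENTS is None:
        _ELEMENTS = element_table()
    return _ELEMENTS


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_seq_number: int
    chain_id: str
    confidence: float


@dataclass
class PeptideGraph:
    nodes: pd.DataFrame  # one row per atom, columns FEATURE_COLUMNS
    edges: np.ndarray  # (n_edges, 2) int array, i < j, lexicographic
    peptide_id: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_features(self) -> np.ndarray:
        return self.nodes[FEATURE_COLUMNS].to_numpy(dtype=np.float64)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in _elements():
        # two-letter symbols only when the name cannot be a remoteness code
        if stripped[:2].upper() in {"SE", "FE", "ZN", "MG", "NA", "CL", "BR"}:
            return stripped[:2].upper()
    return stripped[:1].upper()


def parse_pdb(text: str) -> list[AtomRecord]:
    """Read ATOM records from fixed PDB columns (first MODEL only)."""
    records: list[AtomRecord] = []
    in_trailing_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:6]
        if tag == "ENDMDL":
            in_trailing_model = True  # only the first MODEL is used
            continue
        if in_trailing_model or tag != "ATOM  ":
            continue
        try:
            atom_name = line[12:16].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21].strip()
            residue_seq = int(line[22:26])
            coords = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            bfactor = float(line[60:66])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed ATOM record at line {lineno}") from exc
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(atom_name)
        if element not in _elements():
            raise ValueError(
                f"unresolvable element {element!r} at line {lineno}: {line.rstrip()!r}"
            )
        if not all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates at line {lineno}")
        records.append(
            AtomRecord(
                atom_name=atom_name,
                element=element,
                coords=coords,
                residue_name=residue_name,
                residue_seq_number=residue_seq,
                chain_id=chain_id,
                confidence=bfactor,
            )
        )
    if not records:
        raise ValueError("no ATOM records found in PDB text")
    return records


def mean_confidence(text: str) -> float:
    return float(np.mean([r.confidence for r in parse_pdb(text)]))


def select_best_model(candidates: list[str]) -> int:
    """Index of the candidate PDB with the highest mean per-atom
    confidence; ties break to the lowest index."""
    if not candidates:
        raise ValueError("no candidate structures supplied")
    scores = [mean_confidence(c) for c in candidates]
    return int(np.argmax(scores))  # argmax returns the first maximum


def featurize_atoms(records: list[AtomRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no atoms to featurize")
    table = _elements()
    rows = []
    residue_index = -1
    prev_key = None
    for r in records:
        if r.element not in table:
            raise ValueError(f"no mass/radius entry for element {r.element!r}")
        key = (r.chain_id, r.residue_seq_number)
        if key != prev_key:
            residue_index += 1
            prev_key = key
        info = table[r.element]
        rows.append(
            {
                "x": r.coords[0],
                "y": r.coords[1],
                "z": r.coords[2],
                "atomic_number": info["number"],
                "atomic_mass": info["mass"],
                "atomic_radius": info["covalent_radius"],
                "is_sidechain": int(r.atom_name not in BACKBONE_ATOMS),
                "residue_index": residue_index,
                "atoms_in_residue": 0,  # filled below
                "residue_seq_number": r.residue_seq_number,
            }
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    counts = df.groupby("residue_index")["x"].transform("size")
    df["atoms_in_residue"] = counts.astype(int)
    return df


def build_graph(
    nodes: pd.DataFrame, cutoff: float = 6.0, peptide_id: str = ""
) -> PeptideGraph:
    """Undirected radius graph: an edge joins atoms i != j whose Euclidean
    distance is at most ``cutoff`` Å.  Edges are stored once as (i, j)
    with i < j, sorted lexicographically."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = nodes[["x", "y", "z"]].to_numpy(dtype=np.float64)
    n = len(xyz)
    if n > 1:
        close = squareform(pdist(xyz)) <= cutoff
        iu, ju = np.triu_indices(n, k=1)
        keep = close[iu, ju]
        edges = np.stack([iu[keep], ju[keep]], axis=1)
    else:
        edges = np.empty((0, 2), dtype=int)
    return PeptideGraph(nodes=nodes, edges=edges.astype(int), peptide_id=peptide_id)


def graph_from_pdb(text: str, cutoff: float = 6.0, peptide_id: str = "") -> PeptideGraph:
    return build_graph(featurize_atoms(parse_pdb(text)), cutoff, peptide_id)


def write_graph(graph: PeptideGraph, out_dir) -> None:
    """Debug export: node-feature CSV plus a 0-based `i j` edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = graph.peptide_id or "graph"
    graph.nodes.to_csv(out / f"{stem}.nodes.csv", index=False)
    with open(out / f"{stem}.edges.txt", "w") as fh:
        for i, j in graph.edges:
            fh.write(f"{i} {j}\n")
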