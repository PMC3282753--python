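"""Protein structures and residue-residue contact networks.

Residues are nodes; two residues are in contact when any pair of their
atoms lies within a distance cutoff (6 Å by default).  The resulting
undirected contact network is the substrate onto which response-time
direction information is later imposed.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "ProteinStructure",
    "StructureError",
    "read_structure",
    "contact_network",
    "write_contact_edges",
]


class StructureError(ValueError):
    """Raised for unparseable or empty structures."""


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue with its atom coordinates.

    Parameters
    ----------
    uid : str
        Unique identifier within a structure: chain id + sequence number
        (+ insertion code if present), e.g. ``"A345"``.
    name : str
        Three-letter amino-acid code.
    seq_index : int
        0-based position in the chain ordering of the structure.
    atoms : tuple of (str, ndarray)
        Atom name and Cartesian coordinates in Å.
    """

    uid: str
    name: str
    seq_index: int
    atoms: tuple = ()

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(f"residue {self.uid} has no atoms")
        for atom_name, xyz in self.atoms:
            if not np.all(np.isfinite(xyz)):
                raise StructureError(
                    f"residue {self.uid} atom {atom_name} has non-finite coordinates"
                )

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.asarray([xyz for _, xyz in self.atoms], dtype=float)


@dataclass
class ProteinStructure:
    """An ordered list of residues plus a provenance label."""

    residues: list[Residue] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self):
        if not self.residues:
            raise StructureError("structure contains no residues")
        uids = [r.uid for r in self.residues]
        if len(set(uids)) != len(uids):
            raise StructureError("duplicate residue uids in structure")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def uids(self) -> list[str]:
        return [r.uid for r in self.residues]


def _residue_uid(chain_id: str, resseq: int, icode: str) -> str:
    icode = icode.strip()
    return f"{chain_id}{resseq}{icode}"


def read_structure(pdb_source, chain_filter: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Keeps one residue per (chain, resseq, insertion code) among standard
    amino acids; waters, ligands and other heteroatoms are dropped.
    Alternate locations are resolved to the highest-occupancy conformer
    (Biopython's default atom selection).

    Parameters
    ----------
    pdb_source : path, file-like or str
        A path to a PDB file, an open text handle, or PDB-format text.
    chain_filter : str, optional
        Restrict to a single chain id.

    Raises
    ------
    StructureError
        If the input cannot be parsed, the requested chain is absent, or
        no residues remain after filtering.
    """
    parser = PDBParser(QUIET=True)
    if hasattr(pdb_source, "read"):
        handle, label = pdb_source, "<handle>"
    else:
        text_like = isinstance(pdb_source, str) and "\n" in pdb_source
        if text_like:
            handle, label = io.StringIO(pdb_source), "<text>"
        else:
            path = Path(pdb_source)
            if not path.exists():
                raise StructureError(f"no such PDB file: {path}")
            handle, label = open(path), path.stem

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = next(parser.get_structure(label, handle).get_models())
    except StopIteration:
        raise StructureError(f"{label}: no models in PDB input") from None
    except Exception as exc:  # Biopython raises assorted exceptions on bad input
        raise StructureError(f"{label}: cannot parse PDB input: {exc}") from exc
    finally:
        if handle is not pdb_source:
            handle.close()

    chain_ids = [c.id for c in model]
    if chain_filter is not None and chain_filter not in chain_ids:
        raise StructureError(
            f"{label}: chain {chain_filter!r} not found (chains: {chain_ids})"
        )

    residues: list[Residue] = []
    for chain in model:
        if chain_filter is not None and chain.id != chain_filter:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip() or not is_aa(res, standard=True):
                continue
            atoms = tuple(
                (atom.get_name(), np.asarray(atom.get_coord(), dtype=float))
                for atom in res.get_atoms()
            )
            if not atoms:
                logger.warning("dropping residue %s: no resolvable atoms", res.id)
                continue
            residues.append(
                Residue(
                    uid=_residue_uid(chain.id, resseq, icode),
                    name=res.get_resname(),
                    seq_index=len(residues),
                    atoms=atoms,
                )
            )

    if not residues:
        raise StructureError(f"{label}: no standard amino-acid residues after filtering")
    return ProteinStructure(residues=residues, source_label=label)


def contact_network(structure: ProteinStructure, cutoff_angstrom: float = 6.0) -> nx.Graph:
    """Build the undirected residue contact network.

    An edge joins residues u and v when the minimum over all atom pairs
    of the Euclidean distance is at most ``cutoff_angstrom``.  All atoms
    present in the structure participate; sequence-adjacent residues are
    kept like any other contact.

    Returns
    -------
    networkx.Graph
        Nodes are residue uids (insertion order = sequence order) with
        ``order``, ``resname`` and ``seq_index`` attributes; edges carry
        the minimum atom-pair ``distance``.  The graph attribute
        ``cutoff_angstrom`` records the threshold.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")

    g = nx.Graph(cutoff_angstrom=float(cutoff_angstrom), source_label=structure.source_label)
    for i, res in enumerate(structure.residues):
        g.add_node(res.uid, order=i, resname=res.name, seq_index=res.seq_index)

    coords = np.concatenate([r.coords() for r in structure.residues])
    owner = np.concatenate(
        [np.full(len(r.atoms), i, dtype=int) for i, r in enumerate(structure.residues)]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(cutoff_angstrom), output_type="ndarray")

    uids = structure.uids
    best: dict[tuple[int, int], float] = {}
    if len(pairs):
        ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
        mask = ri != rj
        d = np.linalg.norm(coords[pairs[mask, 0]] - coords[pairs[mask, 1]], axis=1)
        lo = np.minimum(ri[mask], rj[mask])
        hi = np.maximum(ri[mask], rj[mask])
        for a, b, dist in zip(lo, hi, d):
            key = (int(a), int(b))
            if dist < best.get(key, np.inf):
                best[key] = float(dist)
    for (a, b), dist in best.items():
        g.add_edge(uids[a], uids[b], distance=dist)
    return g


def write_contact_edges(g: nx.Graph, path) -> None:
    """Write a contact network as a TSV edge list (uid_a, uid_b, min_distance_A)."""
    with open(path, "w") as fh:
        fh.write("uid_a\tuid_b\tmin_distance_A\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('distance', float('nan')):.3f}\n")
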