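"""Desk-scale synthetic structures and surrogate energy-dissipation runs.

These generators stand in for a crystal structure plus the paired
perturbed/reference molecular-dynamics runs, so the whole network
pipeline can be exercised deterministically at test scale.  The
surrogate dynamics is a discrete linear diffusion of an injected energy
packet over the residue contact graph,

    E_i(t+1) = E_i(t) + alpha * sum_{j in N(i)} (E_j(t) - E_i(t)),

which conserves total energy and produces a monotone wavefront on path
graphs — enough structure to make the downstream direction assignment
and pruning testable against closed-form expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .response import EnergyTraj
from .structure import ProteinStructure, Residue

__all__ = [
    "SurrogateParams",
    "synthetic_structure",
    "surrogate_dissipation",
    "write_pdb",
]

CA_SPACING = 3.8  # consecutive Calpha distance, Å
MIN_SEPARATION = 4.0  # self-avoidance radius between non-consecutive Calphas, Å
RESIDUE_VOLUME = 134.0  # Å^3 per residue, used to size the confining sphere

# pseudo-atom offsets from the Calpha, roughly backbone-bond-length sized
_ATOM_NAMES = ("N", "C", "O", "CB")
_ATOM_RADII = (1.46, 1.52, 2.4, 1.53)


@dataclass
class SurrogateParams:
    """Parameters of the surrogate dissipation run.

    Attributes
    ----------
    diffusion_rate : float or None
        Per-step transfer fraction alpha.  Must satisfy
        ``0 < alpha < 1/max_degree`` for a stable, sign-preserving
        update; ``None`` picks ``0.8 / max_degree`` of the contact
        network at run time.
    perturbation_magnitude : float
        Energy injected into each perturbed residue at t=0 (kcal/mol).
        Stands in for the kinetic-energy kick of the perturbed run.
    noise_sd : float
        SD of additive Gaussian noise per residue and step (kcal/mol).
    n_steps : int
        Number of 1 fs steps; timestamps run 0..n_steps.
    seed : int
        Seed for the noise stream.
    shared_noise : bool
        If True (default) the perturbed and reference runs draw the same
        noise realization, so subtraction cancels it exactly — the
        paired-run design.  Set False to leave residual noise in Δ.
    """

    diffusion_rate: float | None = None
    perturbation_magnitude: float = 1.0
    noise_sd: float = 0.002
    n_steps: int = 200
    seed: int = 0
    shared_noise: bool = True


def synthetic_structure(n_residues: int, seed: int) -> ProteinStructure:
    """Generate a compact self-avoiding chain with pseudo-atoms.

    Consecutive Calphas are placed ~3.8 Å apart inside a confining
    sphere whose volume matches typical protein packing (~134 Å^3 per
    residue), giving 6 Å contact networks with realistic neighbor
    counts.  Each residue carries its Calpha plus four pseudo-atoms at
    bond-length offsets.  Deterministic for a fixed seed.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    radius = (3.0 * n_residues * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)

    ca = np.zeros((n_residues, 3))
    ca[0] = rng.normal(scale=0.5, size=3)
    i = 1
    while i < n_residues:
        placed = False
        for _ in range(200):
            step = rng.normal(size=3)
            # pull back toward the origin when drifting out of the sphere
            dist = np.linalg.norm(ca[i - 1])
            if dist > 0.8 * radius:
                step += 1.5 * (dist / radius) * (-ca[i - 1] / dist)
            step *= CA_SPACING / np.linalg.norm(step)
            cand = ca[i - 1] + step
            prior = ca[: max(i - 1, 0)]
            if len(prior) and np.min(np.linalg.norm(prior - cand, axis=1)) < MIN_SEPARATION:
                continue
            ca[i] = cand
            placed = True
            break
        if placed:
            i += 1
        else:  # dead end: back up one residue and retry
            i = max(i - 1, 1)

    residues = []
    for k in range(n_residues):
        atoms = [("CA", ca[k].copy())]
        for name, r in zip(_ATOM_NAMES, _ATOM_RADII):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append((name, ca[k] + r * direction))
        residues.append(
            Residue(uid=f"A{k + 1}", name="ALA", seq_index=k, atoms=tuple(atoms))
        )
    return ProteinStructure(residues=residues, source_label=f"synthetic(n={n_residues},seed={seed})")


def surrogate_dissipation(
    contacts: nx.Graph,
    perturbed_set,
    params: SurrogateParams | None = None,
) -> tuple[EnergyTraj, EnergyTraj]:
    """Paired perturbed/reference energy trajectories on a contact graph.

    The reference run is pure noise around zero; the perturbed run adds
    the diffusion of ``perturbation_magnitude`` injected at
    ``perturbed_set`` at t=0.  With ``shared_noise`` both runs use one
    noise stream per residue, so the Δ series from
    :func:`dissipnet.response.energy_change` is exactly the noise-free
    diffusion field.
    """
    params = params or SurrogateParams()
    nodes = list(contacts.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    perturbed_set = list(perturbed_set)
    missing = [u for u in perturbed_set if u not in index]
    if not perturbed_set:
        raise ValueError("perturbed_set is empty")
    if missing:
        raise ValueError(f"perturbed residues not in network: {missing}")
    if params.n_steps < 1:
        raise ValueError("n_steps must be >= 1")

    n = len(nodes)
    degrees = np.array([contacts.degree(u) for u in nodes], dtype=float)
    max_deg = degrees.max() if n else 0.0
    alpha = params.diffusion_rate
    if alpha is None:
        alpha = 0.8 / max_deg if max_deg > 0 else 0.1
    if not 0.0 < alpha * max_deg <= 1.0:
        raise ValueError(
            f"diffusion_rate {alpha} unstable for max degree {max_deg:.0f} "
            f"(need 0 < alpha <= 1/max_degree)"
        )

    adj = nx.to_numpy_array(contacts, nodelist=nodes)
    field = np.zeros(n)
    for u in perturbed_set:
        field[index[u]] = params.perturbation_magnitude

    n_t = params.n_steps + 1
    diffusion = np.zeros((n_t, n))
    diffusion[0] = field
    for t in range(1, n_t):
        field = field + alpha * (adj @ field - degrees * field)
        diffusion[t] = field

    rng = np.random.default_rng(params.seed)
    noise_ref = rng.normal(scale=params.noise_sd, size=(n_t, n)) if params.noise_sd > 0 else np.zeros((n_t, n))
    if params.shared_noise or params.noise_sd == 0:
        noise_pert = noise_ref
    else:
        noise_pert = rng.normal(scale=params.noise_sd, size=(n_t, n))

    times = np.arange(n_t, dtype=float)  # fs
    reference = EnergyTraj(
        times=times,
        energies={u: noise_ref[:, index[u]].copy() for u in nodes},
        condition="reference",
    )
    perturbed = EnergyTraj(
        times=times,
        energies={u: diffusion[:, index[u]] + noise_pert[:, index[u]] for u in nodes},
        condition="perturbed",
    )
    return perturbed, reference


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write a structure as minimal but valid PDB text."""
    lines = []
    serial = 1
    for res in structure.residues:
        chain, resseq = res.uid[0], int("".join(c for c in res.uid[1:] if c.isdigit()))
        for atom_name, xyz in res.atoms:
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:5d} {atom_name:^4s}{res.name:>4s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
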