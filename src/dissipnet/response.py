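"""Per-residue energy trajectories and response times.

A perturbed run and a reference run are subtracted residue-by-residue;
the response time of a residue is the first time its absolute energy
change reaches the energy cutoff (0.01 kcal/mol by default).  Residues
that never cross within the recorded horizon carry an "unresponsive"
sentinel, represented as ``math.inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNRESPONSIVE",
    "EnergyTraj",
    "ResponseTimeTable",
    "energy_change",
    "response_times",
    "read_energy_tsv",
    "write_energy_tsv",
    "read_response_tsv",
    "write_response_tsv",
]

#: Sentinel for residues whose energy change never reaches the cutoff.
UNRESPONSIVE = math.inf

DEFAULT_ENERGY_CUTOFF = 0.01  # kcal/mol


@dataclass
class EnergyTraj:
    """Per-residue energy time series for one simulation condition.

    Attributes
    ----------
    times : ndarray, shape (T,)
        Strictly increasing timestamps in femtoseconds.
    energies : dict of str -> ndarray, shape (T,)
        Residue uid to energy series in kcal/mol.
    condition : str
        ``"perturbed"`` or ``"reference"``.
    """

    times: np.ndarray
    energies: dict[str, np.ndarray]
    condition: str = "perturbed"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.energies = {u: np.asarray(e, dtype=float) for u, e in self.energies.items()}
        for uid, series in self.energies.items():
            if series.shape != self.times.shape:
                raise ValueError(
                    f"residue {uid}: series length {len(series)} != {len(self.times)} timestamps"
                )

    @property
    def residues(self) -> list[str]:
        return list(self.energies)


@dataclass
class ResponseTimeTable:
    """Residue response times produced by an energy cutoff.

    ``response_time[uid]`` is the first timestamp (fs) at which
    ``|Δ energy|`` reached ``energy_cutoff``, or :data:`UNRESPONSIVE`.
    """

    response_time: dict[str, float]
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF
    perturbed_set: frozenset[str] = field(default_factory=frozenset)
    horizon: float = float("nan")

    def __post_init__(self):
        self.perturbed_set = frozenset(self.perturbed_set)
        unknown = self.perturbed_set - set(self.response_time)
        if unknown:
            raise ValueError(f"perturbed residues missing from table: {sorted(unknown)}")

    def __getitem__(self, uid: str) -> float:
        return self.response_time[uid]

    def responsive(self) -> dict[str, float]:
        return {u: t for u, t in self.response_time.items() if math.isfinite(t)}


def energy_change(perturbed: EnergyTraj, reference: EnergyTraj) -> EnergyTraj:
    """Δ-energy series: perturbed minus reference, residue by residue.

    Both trajectories must share the same residue set and timestamp grid.
    """
    if set(perturbed.energies) != set(reference.energies):
        only_p = set(perturbed.energies) - set(reference.energies)
        only_r = set(reference.energies) - set(perturbed.energies)
        raise ValueError(
            f"residue sets differ (only perturbed: {sorted(only_p)[:5]}, "
            f"only reference: {sorted(only_r)[:5]})"
        )
    if perturbed.times.shape != reference.times.shape or not np.allclose(
        perturbed.times, reference.times
    ):
        raise ValueError("timestamp grids differ between perturbed and reference runs")
    delta = {
        uid: perturbed.energies[uid] - reference.energies[uid] for uid in perturbed.energies
    }
    return EnergyTraj(times=perturbed.times.copy(), energies=delta, condition="delta")


def response_times(
    delta: EnergyTraj,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    perturbed_set: frozenset[str] | set[str] = frozenset(),
) -> ResponseTimeTable:
    """First-crossing times of ``|Δ| >= energy_cutoff`` per residue.

    The absolute energy change is used: the perturbation may raise or
    lower a residue's energy and either deviation counts as a response.
    """
    if energy_cutoff <= 0:
        raise ValueError("energy cutoff must be positive")
    if not delta.energies:
        raise ValueError("empty Δ-energy series")
    table: dict[str, float] = {}
    for uid, series in delta.energies.items():
        crossed = np.flatnonzero(np.abs(series) >= energy_cutoff)
        table[uid] = float(delta.times[crossed[0]]) if len(crossed) else UNRESPONSIVE
    return ResponseTimeTable(
        response_time=table,
        energy_cutoff=float(energy_cutoff),
        perturbed_set=frozenset(perturbed_set),
        horizon=float(delta.times[-1]),
    )


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def write_energy_tsv(traj: EnergyTraj, path) -> None:
    """Long-format TSV: time_fs, residue_uid, energy_kcal_mol, condition."""
    frames = []
    for uid, series in traj.energies.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_fs": traj.times,
                    "residue_uid": uid,
                    "energy_kcal_mol": series,
                    "condition": traj.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_energy_tsv(path) -> EnergyTraj:
    df = pd.read_csv(path, sep="\t")
    required = {"time_fs", "residue_uid", "energy_kcal_mol", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energy TSV missing columns: {sorted(missing)}")
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(f"energy TSV mixes conditions: {list(conditions)}")
    wide = df.pivot(index="time_fs", columns="residue_uid", values="energy_kcal_mol")
    if wide.isna().any().any():
        raise ValueError("energy TSV has missing (residue, time) combinations")
    wide = wide.sort_index()
    return EnergyTraj(
        times=wide.index.to_numpy(dtype=float),
        energies={str(uid): wide[uid].to_numpy(dtype=float) for uid in wide.columns},
        condition=str(conditions[0]),
    )


def write_response_tsv(table: ResponseTimeTable, path) -> None:
    """TSV: residue_uid, response_time_fs ('unresponsive' for the sentinel)."""
    with open(path, "w") as fh:
        fh.write("residue_uid\tresponse_time_fs\n")
        for uid, t in table.response_time.items():
            out = "unresponsive" if math.isinf(t) else f"{t:.6g}"
            fh.write(f"{uid}\t{out}\n")


def read_response_tsv(path, energy_cutoff: float = DEFAULT_ENERGY_CUTOFF) -> ResponseTimeTable:
    df = pd.read_csv(path, sep="\t", dtype={"residue_uid": str})
    if not {"residue_uid", "response_time_fs"} <= set(df.columns):
        raise ValueError("response TSV needs columns residue_uid, response_time_fs")
    times = {}
    for uid, raw in zip(df["residue_uid"], df["response_time_fs"]):
        times[uid] = UNRESPONSIVE if str(raw) == "unresponsive" else float(raw)
    finite = [t for t in times.values() if math.isfinite(t)]
    return ResponseTimeTable(
        response_time=times,
        energy_cutoff=energy_cutoff,
        horizon=max(finite) if finite else float("nan"),
    )
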