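"""End-to-end pipeline: structure → contacts → response times →
Initial network → pair pruning → layers/PC → statistics.

Driven by a :class:`PipelineConfig` (YAML/JSON round-trippable); every
produced file is listed, with a content hash, in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import analysis, build, hierarchy, pruning, response, structure, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Input is either a PDB file (``pdb``, optional ``chain``) plus a
    pair of energy TSVs (``perturbed_tsv``/``reference_tsv``), or a
    synthetic run (``synthetic_n`` residues, surrogate dynamics seeded
    by ``seed`` and perturbed at the source residues).
    """

    sources: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    output_dir: str = "dissipnet_out"
    contact_cutoff_angstrom: float = 6.0
    energy_cutoff_kcal_mol: float = 0.01
    tie_policy: str = "uid"
    layering_mode: str = "deep"
    pc_degree_scope: str = "network"
    seed: int = 0
    pdb: str | None = None
    chain: str | None = None
    perturbed_tsv: str | None = None
    reference_tsv: str | None = None
    synthetic_n: int | None = None
    surrogate_steps: int = 200
    surrogate_noise_sd: float = 0.002

    def __post_init__(self):
        if self.contact_cutoff_angstrom <= 0 or self.energy_cutoff_kcal_mol <= 0:
            raise ValueError("cutoffs must be positive")
        if self.tie_policy != "uid":
            raise ValueError("only the 'uid' tie policy is implemented")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also covers JSON
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    if not config.sources or not config.targets:
        raise PipelineError("stage config: sources and targets must be non-empty")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return wrap

    # -- structure ---------------------------------------------------------
    def _structure():
        if config.pdb:
            return structure.read_structure(config.pdb, chain_filter=config.chain)
        if config.synthetic_n:
            s = synthetic.synthetic_structure(config.synthetic_n, seed=config.seed)
            synthetic.write_pdb(s, out / "synthetic.pdb")
            produced["structure_pdb"] = out / "synthetic.pdb"
            return s
        raise ValueError("config needs either 'pdb' or 'synthetic_n'")

    struct = stage("structure")(_structure)

    # -- contacts ----------------------------------------------------------
    def _contacts():
        g = structure.contact_network(struct, config.contact_cutoff_angstrom)
        structure.write_contact_edges(g, out / "contacts.tsv")
        produced["contacts_tsv"] = out / "contacts.tsv"
        return g

    contacts = stage("contacts")(_contacts)

    # -- response times ----------------------------------------------------
    def _respond():
        if config.perturbed_tsv and config.reference_tsv:
            pert = response.read_energy_tsv(config.perturbed_tsv)
            ref = response.read_energy_tsv(config.reference_tsv)
            perturbed_set = frozenset()
        else:
            missing = [s for s in config.sources if s not in contacts]
            if missing:
                raise ValueError(f"source residues not in structure: {missing}")
            pert, ref = synthetic.surrogate_dissipation(
                contacts,
                config.sources,
                synthetic.SurrogateParams(
                    n_steps=config.surrogate_steps,
                    noise_sd=config.surrogate_noise_sd,
                    seed=config.seed,
                ),
            )
            perturbed_set = frozenset(config.sources)
        delta = response.energy_change(pert, ref)
        table = response.response_times(
            delta, config.energy_cutoff_kcal_mol, perturbed_set=perturbed_set
        )
        response.write_response_tsv(table, out / "response_times.tsv")
        produced["response_times_tsv"] = out / "response_times.tsv"
        return table

    times = stage("respond")(_respond)

    # -- initial network ---------------------------------------------------
    def _build():
        g = build.direct_network(contacts, times)
        build.write_graphml(g, out / "initial.graphml")
        build.write_directed_edges(g, out / "initial_edges.tsv")
        produced["initial_graphml"] = out / "initial.graphml"
        produced["initial_edges_tsv"] = out / "initial_edges.tsv"
        logger.info("initial network: %d nodes, %d edges, %d tie edges",
                    g.number_of_nodes(), g.number_of_edges(), g.graph["tie_edges"])
        return g

    initial = stage("build")(_build)

    # -- pruning -----------------------------------------------------------
    def _prune():
        missing = [u for u in (*config.sources, *config.targets) if u not in initial]
        if missing:
            raise ValueError(f"sources/targets not in network: {missing}")
        pset = pruning.PairNetworkSet.from_initial(initial, config.sources, config.targets)
        for (s, t), g in pset.pairs.items():
            path = out / f"pair_{s}_{t}.graphml"
            build.write_graphml(g, path)
            produced[f"pair_{s}_{t}"] = path
        build.write_graphml(pset.union, out / "union.graphml")
        build.write_graphml(pset.intersection, out / "intersection.graphml")
        produced["union_graphml"] = out / "union.graphml"
        produced["intersection_graphml"] = out / "intersection.graphml"
        with open(out / "influence_counts.tsv", "w") as fh:
            fh.write("residue_uid\tn_targets\n")
            for u, c in sorted(pset.influence_count.items()):
                fh.write(f"{u}\t{c}\n")
        produced["influence_counts_tsv"] = out / "influence_counts.tsv"
        return pset

    pset = stage("prune")(_prune)

    # -- layers & propagation coefficient ----------------------------------
    def _pc():
        core = pset.intersection
        if core.number_of_nodes() == 0:
            raise ValueError("intersection network is empty; no layers to assign")
        assignment = hierarchy.assign_layers(core, mode=config.layering_mode)
        table = hierarchy.propagation_coefficient(
            core, assignment, degree_scope=config.pc_degree_scope
        )
        table.to_csv(out / "pc.tsv", sep="\t")
        hierarchy.layer_summary(assignment).to_csv(out / "layers.tsv", sep="\t")
        produced["pc_tsv"] = out / "pc.tsv"
        produced["layers_tsv"] = out / "layers.tsv"
        return table

    stage("pc")(_pc)

    # -- statistics --------------------------------------------------------
    def _stats():
        record = {
            name: analysis.network_stats(g).as_dict()
            for name, g in [
                ("initial", initial),
                ("union", pset.union),
                ("intersection", pset.intersection),
            ]
            if g.number_of_nodes() > 0
        }
        (out / "stats.json").write_text(json.dumps(record, indent=2))
        produced["stats_json"] = out / "stats.json"
        return record

    stage("stats")(_stats)

    config.to_file(out / "config.yaml")
    produced["config_yaml"] = out / "config.yaml"
    manifest = {
        "seed": config.seed,
        "tie_edges": initial.graph["tie_edges"],
        "files": {
            key: {"path": str(p), "sha256": _sha256(p)} for key, p in sorted(produced.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
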