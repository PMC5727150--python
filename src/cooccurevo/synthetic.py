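"""Synthetic datasets with the statistical structure the analysis assumes.

The real study rests on thousands of RefSeq genomes; this module replaces
that corpus with simulated data so every downstream stage — system
detection, orthology, tree building, the correlated-evolution test and the
co-occurrence statistics — is testable without downloads:

* Yule (pure-birth) trees with positive branch lengths;
* pairs of binary traits evolved along the tree by event-driven (Gillespie)
  simulation of the joint 4-state chain, under an independent or dependent
  rate regime;
* genome sizes drawn log-normally with trait-dependent means (so the
  genome-size confounder tests have signal to find);
* toy proteomes with planted ortholog families (mutated copies of family
  founder sequences, with optional dropout);
* profile hit tables carrying co-localized component hits exactly for the
  systems each genome's traits say it has (optional decoy singletons).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
stream splitting: the tree, traits, sizes, proteomes and hit table each get
their own child stream, so any stage can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .detection import ProfileHitTable
from .pagel import (
    RateParamsDependent,
    RateParamsIndependent,
    RateParams,
    rate_matrix,
)
from .traits import TraitMatrix
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "DEFAULT_DEPENDENT_RATES",
    "DEFAULT_INDEPENDENT_RATES",
    "DEFAULT_SIZE_MODEL",
    "DEFAULT_COMPONENT_MAP",
    "simulate_tree",
    "simulate_traits",
    "simulate_genome_table",
    "simulate_proteomes",
    "simulate_hit_table",
    "simulate_dataset",
]

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# Strongly negative-association regime: each trait is gained readily when
# the other is absent, gains are rare when the other is present, and the
# doubly-present state decays fast.  This is the generative counterpart of
# the avoidance pattern the co-occurrence analysis looks for.
DEFAULT_DEPENDENT_RATES = RateParamsDependent(
    q00_10=2.0, q00_01=2.0,
    q10_00=1.0, q10_11=0.02,
    q01_00=1.0, q01_11=0.02,
    q11_10=4.0, q11_01=4.0,
)

# Null regime: both traits gained and lost at rate 1, independently.
DEFAULT_INDEPENDENT_RATES = RateParamsIndependent(ax=1.0, bx=1.0, ay=1.0, by=1.0)

# Mean / sd of ln(genome size in bp) per trait combination (x, y).  Trait x
# (the repair system) sits in larger genomes; trait y (the immune system)
# in slightly smaller ones — mirroring the size confounding the statistics
# must cope with.  Roughly 3-4 Mb genomes with ~15% lognormal spread.
DEFAULT_SIZE_MODEL: dict[tuple[int, int], tuple[float, float]] = {
    (0, 0): (np.log(3.0e6), 0.15),
    (0, 1): (np.log(2.8e6), 0.15),
    (1, 0): (np.log(4.0e6), 0.15),
    (1, 1): (np.log(3.8e6), 0.15),
}

DEFAULT_COMPONENT_MAP: dict[str, tuple[str, ...]] = {
    "NHEJ": ("Ku", "LigD"),
    "II-A": ("cas9", "cas1", "cas2", "csn2"),
}


@dataclass
class SimConfig:
    """Generating parameters for one synthetic dataset."""

    n_taxa: int = 30
    birth_rate: float = 1.0
    seed: int = 0
    model_flavor: str = "dependent"
    rates: RateParams | None = None
    root_state: tuple[int, int] = (0, 0)
    size_model: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_MODEL))
    n_families: int = 12
    sub_rate: float = 0.02
    family_dropout: float = 0.05
    component_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_MAP))
    decoy_rate: float = 0.0
    genomes_per_species: int = 1
    phylum: str = "Firmicutes"

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be in [0, 1]")
        if not 0.0 <= self.family_dropout < 1.0:
            raise ValueError("family_dropout must be in [0, 1)")
        if self.model_flavor not in ("independent", "dependent"):
            raise ValueError(f"unknown model_flavor {self.model_flavor!r}")
        if self.rates is None:
            self.rates = (DEFAULT_DEPENDENT_RATES if self.model_flavor == "dependent"
                          else DEFAULT_INDEPENDENT_RATES)
        expected = (RateParamsDependent if self.model_flavor == "dependent"
                    else RateParamsIndependent)
        if not isinstance(self.rates, expected):
            raise ValueError(
                f"rates type {type(self.rates).__name__} does not match "
                f"model_flavor {self.model_flavor!r}"
            )
        if tuple(self.root_state) not in {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise ValueError("root_state must be a pair in {0,1}^2")

    def truth_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = dict(zip(self.rates.names(), self.rates.as_vector().tolist()))
        d["size_model"] = {f"{x}{y}": list(v) for (x, y), v in self.size_model.items()}
        d["component_map"] = {k: list(v) for k, v in self.component_map.items()}
        d["root_state"] = list(self.root_state)
        return d


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_taxa: int, birth_rate: float, seed: int) -> Phylogeny:
    """Yule (pure-birth) tree with ``n_taxa`` tips and positive branch lengths.

    Lineages split at rate ``birth_rate`` each; after the n-th tip appears
    the process runs for one further exponential waiting time, so pendant
    edges have strictly positive length.  Tips are labeled T0001..Tn in
    leaf-traversal order; identical seeds give byte-identical trees.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    root.split_time = 0.0
    active = [root.new_child(), root.new_child()]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.split_time = t
        active.extend([node.new_child(), node.new_child()])
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        end = t if node.is_leaf() else node.split_time
        node.edge.length = end - node.parent_node.split_time
    width = max(4, len(str(n_taxa)))
    tns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(label=f"T{i:0{width}d}")
    return Phylogeny(tree)


def simulate_traits(tree: Phylogeny, rates: RateParams, model_flavor: str,
                    root_state: tuple[int, int], seed: int,
                    return_events: bool = False):
    """Evolve the joint (x, y) chain along the tree by Gillespie simulation.

    Exponential waiting times are drawn from the total exit rate of the
    current joint state along each branch; under the independent flavor the
    embedded chain factorizes, so each trait's events never depend on the
    other's state.  Returns a :class:`TraitMatrix` (and, optionally, the
    per-transition event counts, keyed "s->s'" over states 00,01,10,11).
    """
    expected = (RateParamsDependent if model_flavor == "dependent"
                else RateParamsIndependent)
    if not isinstance(rates, expected):
        raise ValueError(f"rates type does not match model_flavor {model_flavor!r}")
    Q = rate_matrix(rates)
    rng = np.random.default_rng(seed)
    labels = ("00", "01", "10", "11")
    events = {f"{labels[i]}->{labels[j]}": 0 for i in range(4) for j in range(4)
              if i != j and Q[i, j] > 0}
    x, y = root_state
    root_idx = 2 * int(x) + int(y)
    states: dict[str, tuple[int, int]] = {}
    dtree = tree.dendropy_tree
    node_state = {id(dtree.seed_node): root_idx}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        s = node_state[id(node.parent_node)]
        remaining = float(node.edge.length)
        while True:
            total = -Q[s, s]
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            if dt > remaining:
                break
            remaining -= dt
            probs = Q[s].copy()
            probs[s] = 0.0
            nxt = int(rng.choice(4, p=probs / total))
            events[f"{labels[s]}->{labels[nxt]}"] += 1
            s = nxt
        node_state[id(node)] = s
        if node.is_leaf():
            states[node.taxon.label] = (s >> 1, s & 1)
    tm = TraitMatrix(states=states)
    return (tm, events) if return_events else tm


def simulate_genome_table(traits: TraitMatrix, size_model, seed: int,
                          genomes_per_species: int = 1,
                          phylum: str = "Firmicutes") -> pd.DataFrame:
    """Genome metadata (species, phylum, size) consistent with the traits.

    Sizes are lognormal with trait-combination-specific (mean, sd) of the
    log size.  ``genomes_per_species`` > 1 groups consecutive genomes into
    shared species labels, for exercising species-level aggregation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (gid, (x, y)) in enumerate(traits.states.items()):
        if x is None or y is None:
            raise ValueError(f"genome {gid!r} has a missing trait state")
        mu, sd = size_model[(x, y)]
        size = int(round(np.exp(rng.normal(mu, sd))))
        species = f"sp{(i // genomes_per_species) + 1:04d}"
        rows.append((gid, species, phylum, size, x, y))
    return pd.DataFrame(
        rows, columns=["genome_id", "species", "phylum", "size_bp",
                       traits.x_name, traits.y_name]
    )


@dataclass
class ProteomeTruth:
    """Founder sequences and the planted family membership."""

    founders: dict[str, str]  # family_id -> founder sequence
    members: dict[str, dict[str, str]]  # family_id -> {genome_id: protein_id}
    dropped: list[tuple[str, str]]  # (family_id, genome_id) omissions


def _mutate(seq: np.ndarray, sub_rate: float, rng: np.random.Generator) -> np.ndarray:
    if sub_rate == 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < sub_rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_proteomes(genome_ids, n_families: int, sub_rate: float,
                       family_dropout: float, seed: int,
                       length_range: tuple[int, int] = (120, 300),
                       ) -> tuple[dict[str, dict[str, str]], ProteomeTruth]:
    """Toy proteomes: mutated copies of planted family founders.

    Each genome carries one copy of every family it has not dropped; each
    copy position mutates independently with probability ``sub_rate``.
    Returns ({genome_id: {protein_id: sequence}}, truth record).
    """
    genome_ids = [str(g) for g in genome_ids]
    if not genome_ids:
        raise ValueError("genome_ids must be nonempty")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 <= family_dropout < 1.0:
        raise ValueError("family_dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    founders: dict[str, np.ndarray] = {}
    for k in range(n_families):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        founders[f"fam{k + 1:03d}"] = rng.choice(AMINO_ACIDS, size=length)
    proteomes: dict[str, dict[str, str]] = {g: {} for g in genome_ids}
    members: dict[str, dict[str, str]] = {f: {} for f in founders}
    dropped: list[tuple[str, str]] = []
    for fam, founder in founders.items():
        for gid in genome_ids:
            if rng.random() < family_dropout:
                dropped.append((fam, gid))
                continue
            pid = f"{gid}|{fam}"
            proteomes[gid][pid] = _mutate(founder, sub_rate, rng).tobytes().decode()
            members[fam][gid] = pid
    truth = ProteomeTruth(
        founders={f: s.tobytes().decode() for f, s in founders.items()},
        members=members,
        dropped=dropped,
    )
    return proteomes, truth


def simulate_hit_table(traits: TraitMatrix, component_map, seed: int,
                       decoy_rate: float = 0.0) -> ProfileHitTable:
    """Profile hits implied by the traits: co-localized components per system.

    Genomes with a trait carry its components at adjacent gene ranks on
    the chromosome; genomes without it carry none.  ``decoy_rate`` > 0
    plants, per absent system and genome, a lone component hit with that
    probability — sub-quorum noise that detection must ignore.
    """
    trait_names = (traits.x_name, traits.y_name)
    unknown = set(component_map) - set(trait_names)
    if unknown:
        raise ValueError(
            f"component_map keys {sorted(unknown)} not among traits {trait_names}"
        )
    missing = set(trait_names) - set(component_map)
    if missing:
        raise ValueError(f"component_map lacks entries for traits {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for gid, (x, y) in traits.states.items():
        if x is None or y is None:
            raise ValueError(f"genome {gid!r} has a missing trait state")
        base_rank = 10
        for name, state in zip(trait_names, (x, y)):
            comps = component_map[name]
            if state == 1:
                for j, comp in enumerate(comps):
                    rows.append((gid, "chromosome", base_rank + j, comp,
                                 float(np.round(rng.uniform(30, 100), 2))))
            elif decoy_rate > 0 and rng.random() < decoy_rate:
                lone = comps[int(rng.integers(len(comps)))]
                rows.append((gid, "chromosome", base_rank + 50, lone,
                             float(np.round(rng.uniform(30, 100), 2))))
            base_rank += 200
    df = pd.DataFrame(rows, columns=["genome_id", "replicon", "gene_rank",
                                     "component", "score"])
    return ProfileHitTable(df)


@dataclass
class SimulatedDataset:
    """One fully simulated study: tree, traits, metadata, proteomes, hits."""

    config: SimConfig
    tree: Phylogeny
    traits: TraitMatrix
    genome_table: pd.DataFrame
    proteomes: dict[str, dict[str, str]]
    hit_table: ProfileHitTable
    truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        (out / "traits.tsv").write_text(self.traits.to_tsv())
        self.genome_table.to_csv(out / "genomes.tsv", sep="\t", index=False)
        (out / "hits.tsv").write_text(self.hit_table.to_tsv())
        prot_dir = out / "proteomes"
        prot_dir.mkdir(exist_ok=True)
        for gid, prots in self.proteomes.items():
            with open(prot_dir / f"{gid}.faa", "w") as fh:
                for pid, seq in prots.items():
                    fh.write(f">{pid}\n{seq}\n")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete dataset from one :class:`SimConfig`.

    Deterministic in ``config.seed``; tip labels are shared across the
    tree, traits, genome table, proteomes and hit table.
    """
    tree_rng, trait_rng, size_rng, prot_rng, hit_rng = (
        s.generate_state(1)[0] for s in np.random.SeedSequence(config.seed).spawn(5)
    )
    tree = simulate_tree(config.n_taxa, config.birth_rate, tree_rng)
    traits = simulate_traits(tree, config.rates, config.model_flavor,
                             config.root_state, trait_rng)
    x_name, y_name = tuple(config.component_map)[:2] if len(config.component_map) >= 2 \
        else (traits.x_name, traits.y_name)
    traits = TraitMatrix(states=traits.states, x_name=x_name, y_name=y_name)
    genome_table = simulate_genome_table(
        traits, config.size_model, size_rng,
        genomes_per_species=config.genomes_per_species, phylum=config.phylum)
    proteomes, prot_truth = simulate_proteomes(
        traits.labels, config.n_families, config.sub_rate,
        config.family_dropout, prot_rng)
    hit_table = simulate_hit_table(traits, config.component_map, hit_rng,
                                   decoy_rate=config.decoy_rate)
    truth = {
        "config": config.truth_dict(),
        "tip_states": {g: list(s) for g, s in traits.states.items()},
        "founders": prot_truth.founders,
        "family_members": prot_truth.members,
        "dropped_families": [list(x) for x in prot_truth.dropped],
    }
    return SimulatedDataset(
        config=config, tree=tree, traits=traits, genome_table=genome_table,
        proteomes=proteomes, hit_table=hit_table, truth=truth,
    )
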