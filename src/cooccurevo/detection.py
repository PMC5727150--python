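"""Quorum-based detection of macromolecular systems from component hit tables.

A *system model* declares which protein components are mandatory,
accessory or forbidden for a system (e.g. NHEJ: Ku mandatory, LigD
accessory), how many mandatory components constitute a quorum, and how
tightly components must co-localize along a replicon.  Presence/absence
is then called per genome from a table of profile hits — the abstracted
output of a profile-search tool, taken at face value (no score
filtering; profile scanning itself is out of scope).

Type II CRISPR-Cas subtypes are classified from marker genes: csn2 marks
II-A, cas4 marks II-B, and a system with only the core cas1/cas2/cas9 is
II-C.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .traits import TraitMatrix

__all__ = [
    "SystemModel",
    "ProfileHitTable",
    "DetectionResult",
    "SubtypeAmbiguityError",
    "load_system_model",
    "save_system_model",
    "packaged_model",
    "detect_system",
    "detect_all",
    "classify_type_ii_subtype",
    "build_trait_table",
]

HIT_COLUMNS = ("genome_id", "replicon", "gene_rank", "component", "score")

_MODEL_KEYS = {"name", "mandatory", "accessory", "forbidden",
               "min_mandatory", "colocalization_window"}


class SubtypeAmbiguityError(ValueError):
    """Both II-A and II-B marker genes found in one system."""


@dataclass(frozen=True)
class SystemModel:
    """Declarative component-quorum rules for one system."""

    name: str
    mandatory: frozenset[str]
    accessory: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()
    min_mandatory: int = 1
    colocalization_window: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mandatory", frozenset(self.mandatory))
        object.__setattr__(self, "accessory", frozenset(self.accessory))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        if not self.mandatory:
            raise ValueError("a system model needs at least one mandatory component")
        if self.mandatory & self.accessory:
            raise ValueError(
                f"components cannot be both mandatory and accessory: "
                f"{sorted(self.mandatory & self.accessory)}"
            )
        if (self.mandatory | self.accessory) & self.forbidden:
            raise ValueError("forbidden components overlap mandatory/accessory")
        if not (1 <= self.min_mandatory <= len(self.mandatory)):
            raise ValueError(
                f"min_mandatory={self.min_mandatory} out of range for "
                f"{len(self.mandatory)} mandatory component(s)"
            )
        if self.colocalization_window < 1:
            raise ValueError("colocalization_window must be >= 1")

    @property
    def components(self) -> frozenset[str]:
        return self.mandatory | self.accessory

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mandatory": sorted(self.mandatory),
            "accessory": sorted(self.accessory),
            "forbidden": sorted(self.forbidden),
            "min_mandatory": self.min_mandatory,
            "colocalization_window": self.colocalization_window,
        }


def _model_from_dict(raw: dict, source: str) -> SystemModel:
    if not isinstance(raw, dict):
        raise ValueError(f"{source}: model file must hold a mapping")
    unknown = set(raw) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    if "name" not in raw or "mandatory" not in raw:
        raise ValueError(f"{source}: 'name' and 'mandatory' are required")
    return SystemModel(
        name=str(raw["name"]),
        mandatory=frozenset(raw["mandatory"]),
        accessory=frozenset(raw.get("accessory", [])),
        forbidden=frozenset(raw.get("forbidden", [])),
        min_mandatory=int(raw.get("min_mandatory", 1)),
        colocalization_window=int(raw.get("colocalization_window", 5)),
    )


def load_system_model(path: str | Path) -> SystemModel:
    """Load a system model from a YAML (or JSON) file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return _model_from_dict(raw, str(path))


def save_system_model(model: SystemModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def packaged_model(name: str) -> SystemModel:
    """Load one of the shipped models: ``nhej`` or ``cas_type_ii``."""
    ref = resources.files("cooccurevo.models") / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return _model_from_dict(raw, f"packaged:{name}")


@dataclass
class ProfileHitTable:
    """Rows of (genome_id, replicon, gene_rank, component, score).

    ``gene_rank`` is the 1-based position of the gene along its replicon;
    co-localization is judged on these ranks.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df, columns=list(HIT_COLUMNS)) if len(self.df) else \
            pd.DataFrame(columns=list(HIT_COLUMNS))
        missing = set(HIT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        df = df.loc[:, list(HIT_COLUMNS)].copy()
        df["gene_rank"] = df["gene_rank"].astype(int)
        df["score"] = df["score"].astype(float)
        if len(df) and (df["gene_rank"] < 1).any():
            raise ValueError("gene_rank must be >= 1")
        key = ["genome_id", "replicon", "gene_rank", "component"]
        if len(df) and df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValueError(
                f"duplicate hit row: {tuple(dup[k] for k in key)}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.df["genome_id"].unique())

    def for_genome(self, genome_id: str) -> "ProfileHitTable":
        return ProfileHitTable(self.df[self.df["genome_id"] == genome_id])

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ProfileHitTable":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        return cls(df)


@dataclass(frozen=True)
class DetectionResult:
    """Per-genome presence call for one system."""

    genome_id: str
    system_name: str
    present: bool
    components_found: frozenset[str]
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.subtype is not None and not self.present:
            raise ValueError("subtype can only be set for present systems")


def _clusters(sub: pd.DataFrame, window: int):
    """Split model-component hits on one replicon into co-localized clusters.

    Two consecutive hits stay in one cluster when at most ``window`` genes
    intervene between them (rank difference <= window + 1).
    """
    sub = sub.sort_values(["gene_rank", "component"])
    cluster: list[tuple[int, str]] = []
    prev = None
    for _, row in sub.iterrows():
        rank, comp = int(row["gene_rank"]), str(row["component"])
        if prev is not None and rank - prev - 1 > window:
            yield cluster
            cluster = []
        cluster.append((rank, comp))
        prev = rank
    if cluster:
        yield cluster


def detect_system(hits: ProfileHitTable | pd.DataFrame, model: SystemModel,
                  classify_subtype: bool = False) -> DetectionResult:
    """Call one system in one genome's hits.

    The system is present iff some replicon carries a co-localized cluster
    with at least ``min_mandatory`` distinct mandatory components and no
    forbidden component.  ``components_found`` is the union of model
    components over all valid clusters.
    """
    df = hits.df if isinstance(hits, ProfileHitTable) else ProfileHitTable(hits).df
    genomes = df["genome_id"].unique()
    if len(genomes) > 1:
        raise ValueError(f"hits span multiple genomes: {sorted(genomes)[:5]}")
    genome_id = str(genomes[0]) if len(genomes) else "<no-hits>"
    relevant = df[df["component"].isin(model.components | model.forbidden)]
    found: set[str] = set()
    present = False
    for _, sub in relevant.groupby("replicon"):
        for cluster in _clusters(sub, model.colocalization_window):
            comps = {c for _, c in cluster}
            if comps & model.forbidden:
                continue
            if len(comps & model.mandatory) >= model.min_mandatory:
                present = True
                found |= comps & model.components
    subtype = None
    if classify_subtype and present and "cas9" in found:
        subtype = classify_type_ii_subtype(found)
    return DetectionResult(
        genome_id=genome_id,
        system_name=model.name,
        present=present,
        components_found=frozenset(found),
        subtype=subtype,
    )


def detect_all(hit_table: ProfileHitTable, model: SystemModel,
               genome_ids, classify_subtype: bool = False) -> list[DetectionResult]:
    """Call one system across an explicit genome universe.

    Genomes in ``genome_ids`` without any hits get an absent call; hits
    for genomes outside the universe are an error (likely a join bug).
    """
    genome_ids = [str(g) for g in genome_ids]
    stray = set(hit_table.genome_ids) - set(genome_ids)
    if stray:
        raise ValueError(f"hit table has genomes outside the universe: {sorted(stray)[:5]}")
    results = []
    for gid in genome_ids:
        sub = hit_table.df[hit_table.df["genome_id"] == gid]
        if len(sub) == 0:
            results.append(DetectionResult(gid, model.name, False, frozenset()))
        else:
            res = detect_system(ProfileHitTable(sub), model, classify_subtype)
            results.append(res)
    return results


def classify_type_ii_subtype(components_found) -> str:
    """II-A (csn2), II-B (cas4) or II-C (core genes only).

    A system carrying both subtype markers is ambiguous and raises rather
    than guessing.
    """
    comps = set(components_found)
    if "cas9" not in comps:
        raise ValueError("subtype classification requires a cas9-bearing system")
    has_csn2 = "csn2" in comps
    has_cas4 = "cas4" in comps
    if has_csn2 and has_cas4:
        raise SubtypeAmbiguityError(
            "both csn2 (II-A marker) and cas4 (II-B marker) present"
        )
    if has_csn2:
        return "II-A"
    if has_cas4:
        return "II-B"
    return "II-C"


def build_trait_table(detections, trait_x_system: str, trait_y_system: str,
                      subtype_x: str | None = None,
                      subtype_y: str | None = None) -> TraitMatrix:
    """Binary (x, y) trait pairs per genome from detection results.

    ``subtype_y`` (or ``subtype_x``) restricts a trait to one subtype:
    e.g. trait_y_system="cas_type_II", subtype_y="II-A" scores a genome 1
    only if its type II system is present *and* classified II-A.
    """
    calls: dict[str, dict[str, DetectionResult]] = {}
    for det in detections:
        calls.setdefault(det.genome_id, {})[det.system_name] = det
    if not calls:
        raise ValueError("no detection results given")

    def state(det: DetectionResult | None, subtype: str | None) -> int:
        if det is None or not det.present:
            return 0
        if subtype is not None and det.subtype != subtype:
            return 0
        return 1

    missing = sorted(
        g for g, c in calls.items()
        if trait_x_system not in c or trait_y_system not in c
    )
    if missing:
        raise ValueError(
            f"genomes missing a call for {trait_x_system!r} or "
            f"{trait_y_system!r}: {missing[:10]}"
        )
    x_name = trait_x_system if subtype_x is None else f"{trait_x_system}:{subtype_x}"
    y_name = trait_y_system if subtype_y is None else f"{trait_y_system}:{subtype_y}"
    states = {
        g: (state(c[trait_x_system], subtype_x), state(c[trait_y_system], subtype_y))
        for g, c in calls.items()
    }
    return TraitMatrix(states=states, x_name=x_name, y_name=y_name)
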