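"""Synthetic multi-species torpor expression data with known latent structure.

The generator emulates the structure of real heterotherm hibernation
studies: two "species", several tissues, the physiological states
euthermia / torpor / IBA (interbout arousal) with a few replicates each,
partially shared latent expression programs across species, and
per-sample sequencing-depth artifacts.  The planted model is

    X = (A_true · P_true) ⊙ noise ⊙ depth

with multiplicative lognormal noise (keeps TPM-like values
non-negative), a lognormal per-sample depth factor, and lognormal
per-gene baselines.  On top of the i.i.d. noise, each sample carries a
coherent idiosyncratic module — one random-sign factor of bounded log
magnitude applied to a random gene subset — emulating individual-animal
variability between replicates; this is the variation that
over-factorized fits pick up as sample-specific patterns.  Baseline
expression is carried inside the tissue pattern columns (each sample
belongs to exactly one tissue), so the planted matrix has rank exactly
k_true and every pattern is recoverable.  Shared patterns place
identical amplitudes on ortholog-paired marker genes in both species; a
species-private pattern is a distinct program (own tissue x state cell,
own ortholog marker genes) present in one species and entirely absent
from the other.  Sample weights are 0/1 indicators of the pattern's
tissue/state condition plus a small uniform jitter, giving crisp ground
truth for eta²-based classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    FLOAT_FORMAT,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    SampleAnnotation,
    read_expression_tsv,
    read_gmt,
    read_oma_orthologs,
    read_sample_annotations,
    write_expression_tsv,
    write_gmt,
    write_oma_orthologs,
    write_sample_annotations,
)

__all__ = [
    "PatternSpec",
    "SyntheticScenario",
    "SyntheticDataset",
    "SyntheticTruth",
    "SyntheticBundle",
    "default_patterns",
    "generate_scenario",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


@dataclass(frozen=True)
class PatternSpec:
    """One planted latent program.

    kind: "tissue" (active in one tissue, all states), "state" (active in
    one state, all tissues) or "tissue_state" (active in one tissue x
    state cell).  ``shared`` patterns use the same ortholog marker genes
    and amplitudes in both species; a private pattern belongs to exactly
    one species (``species``), with its own marker genes, and is entirely
    absent from the other species.
    """

    name: str
    kind: str  # tissue | state | tissue_state
    tissue: str | None = None
    state: str | None = None
    shared: bool = True
    species: str | None = None  # owner of a private pattern

    def __post_init__(self) -> None:
        if self.kind not in ("tissue", "state", "tissue_state"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind in ("tissue", "tissue_state") and not self.tissue:
            raise ValueError(f"pattern {self.name!r}: tissue required")
        if self.kind in ("state", "tissue_state") and not self.state:
            raise ValueError(f"pattern {self.name!r}: state required")
        if not self.shared and not self.species:
            raise ValueError(
                f"pattern {self.name!r}: a private pattern needs an owner species"
            )


def default_patterns(
    tissues: tuple[str, ...] = ("brain", "liver", "muscle"),
) -> tuple[PatternSpec, ...]:
    """Default planted programs, k_true = 6 per species: three shared
    tissue programs, shared torpor and IBA (interbout arousal) programs,
    and one private tissue x torpor program per species (different cell
    and different genes in each species)."""
    tissue_patterns = tuple(
        PatternSpec(name=f"tissue_{t}", kind="tissue", tissue=t) for t in tissues
    )
    return tissue_patterns + (
        PatternSpec(name="state_torpor", kind="state", state="torpor"),
        PatternSpec(name="state_IBA", kind="state", state="IBA"),
        PatternSpec(
            name="private_speciesA_liver_torpor", kind="tissue_state",
            tissue="liver", state="torpor", shared=False, species="speciesA",
        ),
        PatternSpec(
            name="private_speciesB_muscle_torpor", kind="tissue_state",
            tissue="muscle", state="torpor", shared=False, species="speciesB",
        ),
    )


@dataclass
class SyntheticScenario:
    """Study conditions for one simulated multi-species experiment."""

    n_species: int = 2
    genes_per_species: int = 2000
    ortholog_fraction: float = 0.7
    tissues: tuple[str, ...] = ("brain", "liver", "muscle")
    states: tuple[str, ...] = ("euthermia", "torpor", "IBA")
    replicates: int = 3
    patterns: tuple[PatternSpec, ...] = field(default_factory=default_patterns)
    effect_size: float = 2.0  # marker amplitude relative to baseline
    noise_sd: float = 0.1  # log-scale multiplicative noise
    depth_factor_sd: float = 0.1  # log-scale per-sample depth factor
    sample_effect_sd: float = 0.8  # max log-magnitude of a sample's module effect
    sample_effect_fraction: float = 0.1  # fraction of genes in each sample's module
    marker_log_mean: float = 3.5  # marker genes are solidly expressed ...
    marker_log_sd: float = 0.5  # ... with moderate spread
    marker_genes_per_pattern: int = 50
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.5
    jitter_max: float = 0.1  # uniform jitter on sample weights, <=10% of effect
    seed: int = 0

    def patterns_of(self, species: str) -> tuple[PatternSpec, ...]:
        return tuple(
            p for p in self.patterns if p.shared or p.species == species
        )

    @property
    def k_true(self) -> int:
        """Planted pattern count per species (shared + own private)."""
        counts = {
            sp: len(self.patterns_of(sp)) for sp in _SPECIES_NAMES[: self.n_species]
        }
        if len(set(counts.values())) != 1:
            raise ValueError(f"species have unequal pattern counts: {counts}")
        return next(iter(counts.values()))

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.states) * self.replicates

    def validate(self) -> None:
        if self.n_species != 2:
            raise ValueError("exactly 2 species are supported")
        if self.genes_per_species <= 0 or self.replicates <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.ortholog_fraction <= 1):
            raise ValueError("ortholog_fraction must be in (0, 1]")
        if not (0 <= self.sample_effect_fraction < 1):
            raise ValueError("sample_effect_fraction must be in [0, 1)")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        if len({p.name for p in self.patterns}) != len(self.patterns):
            raise ValueError("pattern names must be unique")
        if self.k_true > min(self.genes_per_species, self.n_samples):
            raise ValueError("k_true exceeds min(genes, samples)")
        valid_species = set(_SPECIES_NAMES[: self.n_species])
        for p in self.patterns:
            if p.tissue is not None and p.tissue not in self.tissues:
                raise ValueError(f"pattern {p.name!r}: unknown tissue {p.tissue!r}")
            if p.state is not None and p.state not in self.states:
                raise ValueError(f"pattern {p.name!r}: unknown state {p.state!r}")
            if not p.shared and p.species not in valid_species:
                raise ValueError(
                    f"pattern {p.name!r}: unknown owner species {p.species!r}"
                )
        n_orth = int(round(self.ortholog_fraction * self.genes_per_species))
        need = len(self.patterns) * self.marker_genes_per_pattern
        if need > n_orth:
            raise ValueError(
                f"marker blocks need {need} ortholog genes but only "
                f"{n_orth} are available"
            )

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "genes_per_species": self.genes_per_species,
            "ortholog_fraction": self.ortholog_fraction,
            "tissues": list(self.tissues),
            "states": list(self.states),
            "replicates": self.replicates,
            "patterns": [
                {
                    "name": p.name, "kind": p.kind, "tissue": p.tissue,
                    "state": p.state, "shared": p.shared, "species": p.species,
                }
                for p in self.patterns
            ],
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "depth_factor_sd": self.depth_factor_sd,
            "sample_effect_sd": self.sample_effect_sd,
            "sample_effect_fraction": self.sample_effect_fraction,
            "marker_log_mean": self.marker_log_mean,
            "marker_log_sd": self.marker_log_sd,
            "marker_genes_per_pattern": self.marker_genes_per_pattern,
            "baseline_log_mean": self.baseline_log_mean,
            "baseline_log_sd": self.baseline_log_sd,
            "jitter_max": self.jitter_max,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        if "patterns" in d:
            d["patterns"] = tuple(
                PatternSpec(**p) if isinstance(p, dict) else p for p in d["patterns"]
            )
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        if "states" in d:
            d["states"] = tuple(d["states"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    species: str
    expression: ExpressionMatrix
    annotations: list[SampleAnnotation]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    A_true: dict[str, pd.DataFrame]  # species -> genes x patterns
    P_true: dict[str, pd.DataFrame]  # species -> patterns x samples
    markers: dict[str, dict[str, list[str]]]  # species -> pattern -> gene ids
    depth_factors: dict[str, pd.Series]  # species -> per-sample factor
    shared_flags: dict[str, bool]  # pattern name -> shared across species
    seed: int


@dataclass
class SyntheticBundle:
    scenario: SyntheticScenario
    datasets: dict[str, SyntheticDataset]
    ortholog_map: OrthologMap
    truth: SyntheticTruth

    @property
    def species(self) -> list[str]:
        return list(self.datasets)


_SPECIES_NAMES = ("speciesA", "speciesB")


def _sample_ids(scenario: SyntheticScenario, species: str) -> list[tuple[str, str, str, str]]:
    out = []
    for tissue in scenario.tissues:
        for state in scenario.states:
            for rep in range(1, scenario.replicates + 1):
                out.append((f"{species}_{tissue}_{state}_r{rep}", tissue, state, str(rep)))
    return out


def generate_scenario(scenario: SyntheticScenario) -> SyntheticBundle:
    """Simulate both species' expression matrices plus full ground truth.

    Fully determined by ``scenario.seed``: the same scenario always yields
    identical matrices, annotations, ortholog map and truth.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n_genes = scenario.genes_per_species
    n_orth = int(round(scenario.ortholog_fraction * n_genes))
    m = scenario.marker_genes_per_pattern
    species = list(_SPECIES_NAMES[: scenario.n_species])

    gene_ids = {
        sp: [f"{sp}_g{i:05d}" for i in range(1, n_genes + 1)] for sp in species
    }
    # ortholog pairs: index-matched genes among the first n_orth
    omap = OrthologMap(
        species_a=species[0],
        species_b=species[1],
        pairs=[(gene_ids[species[0]][i], gene_ids[species[1]][i]) for i in range(n_orth)],
    )

    # one disjoint marker block per planted pattern, all among ortholog
    # genes (so cross-species restriction keeps every planted program)
    cursor = 0
    blocks: dict[str, np.ndarray] = {}
    for p in scenario.patterns:
        blocks[p.name] = np.arange(cursor, cursor + m)
        cursor += m

    # baselines: ortholog pairs share one ancestral baseline, the rest are
    # species-specific draws; marker genes get their own (tighter, solidly
    # expressed) baseline distribution so planted programs have stable energy
    baseline_orth = rng.lognormal(scenario.baseline_log_mean, scenario.baseline_log_sd, n_orth)
    baseline_orth[:cursor] = rng.lognormal(
        scenario.marker_log_mean, scenario.marker_log_sd, cursor
    )
    baselines = {}
    for sp in species:
        own = rng.lognormal(
            scenario.baseline_log_mean, scenario.baseline_log_sd, n_genes - n_orth
        )
        baselines[sp] = np.concatenate([baseline_orth, own])

    tissue_kinds = {p.tissue for p in scenario.patterns if p.kind == "tissue"}
    missing_tissue = [t for t in scenario.tissues if t not in tissue_kinds]
    if missing_tissue:
        raise ValueError(
            f"every tissue needs a tissue pattern to carry baseline "
            f"expression; missing: {missing_tissue}"
        )

    datasets: dict[str, SyntheticDataset] = {}
    A_true: dict[str, pd.DataFrame] = {}
    P_true: dict[str, pd.DataFrame] = {}
    markers: dict[str, dict[str, list[str]]] = {}
    depth_factors: dict[str, pd.Series] = {}

    for sp in species:
        sp_patterns = scenario.patterns_of(sp)
        pattern_names = [p.name for p in sp_patterns]
        samples = _sample_ids(scenario, sp)
        sids = [s[0] for s in samples]
        base = baselines[sp]

        A = np.zeros((n_genes, len(sp_patterns)))
        sp_markers: dict[str, list[str]] = {}
        for j, p in enumerate(sp_patterns):
            if p.kind == "tissue":
                A[:, j] = base  # baseline rides on the tissue programs
            block = blocks[p.name]
            A[block, j] += scenario.effect_size * base[block]
            sp_markers[p.name] = [gene_ids[sp][i] for i in block]

        P = np.zeros((len(sp_patterns), len(sids)))
        for j, p in enumerate(sp_patterns):
            for c, (_, tissue, state, _) in enumerate(samples):
                on = (p.tissue is None or p.tissue == tissue) and (
                    p.state is None or p.state == state
                )
                P[j, c] = 1.0 if on else 0.0
        P += rng.uniform(0.0, scenario.jitter_max, size=P.shape)

        X = A @ P
        if scenario.noise_sd > 0:
            X = X * rng.lognormal(0.0, scenario.noise_sd, size=X.shape)
        if scenario.sample_effect_sd > 0 and scenario.sample_effect_fraction > 0:
            # coherent individual-animal module: one up- or down-factor of
            # fixed log magnitude on a random gene subset per sample, drawn
            # from below the top expression decile (extreme per-animal
            # modules are not the housekeeping genes)
            n_mod = int(round(scenario.sample_effect_fraction * n_genes))
            eligible = np.nonzero(base <= np.quantile(base, 0.9))[0]
            n_mod = min(n_mod, len(eligible))
            for c in range(len(sids)):
                idx = rng.choice(eligible, size=n_mod, replace=False)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                magnitude = rng.uniform(0.0, scenario.sample_effect_sd)
                X[idx, c] *= float(np.exp(sign * magnitude))
        depth = (
            rng.lognormal(0.0, scenario.depth_factor_sd, size=len(sids))
            if scenario.depth_factor_sd > 0
            else np.ones(len(sids))
        )
        X = X * depth[None, :]

        expr = ExpressionMatrix(gene_ids=list(gene_ids[sp]), sample_ids=sids, values=X)
        libsize = X.sum(axis=0)
        anns = [
            SampleAnnotation(
                sample_id=sid, dataset=sp, tissue=tissue, state=state,
                replicate=rep, library_size=float(libsize[c]),
            )
            for c, (sid, tissue, state, rep) in enumerate(samples)
        ]
        datasets[sp] = SyntheticDataset(species=sp, expression=expr, annotations=anns)
        A_true[sp] = pd.DataFrame(A, index=gene_ids[sp], columns=pattern_names)
        P_true[sp] = pd.DataFrame(P, index=pattern_names, columns=sids)
        markers[sp] = sp_markers
        depth_factors[sp] = pd.Series(depth, index=sids)

    truth = SyntheticTruth(
        A_true=A_true,
        P_true=P_true,
        markers=markers,
        depth_factors=depth_factors,
        shared_flags={p.name: p.shared for p in scenario.patterns},
        seed=scenario.seed,
    )
    return SyntheticBundle(
        scenario=scenario, datasets=datasets, ortholog_map=omap, truth=truth
    )


def write_fixture_bundle(
    bundle: SyntheticBundle, directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Emit every file dialect the io layer reads, plus a truth sidecar.

    Writes per-species expression and annotation TSVs, OMA-dialect
    ortholog files, a GMT of planted marker sets (one set per planted
    pattern, in the namespace of the species where it is planted) and a
    JSON truth sidecar with A_true / P_true as TSVs.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace"
        )
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for sp, ds in bundle.datasets.items():
        p_expr = directory / f"expression_{sp}.tsv"
        p_ann = directory / f"annotations_{sp}.tsv"
        write_expression_tsv(ds.expression, p_expr)
        write_sample_annotations(ds.annotations, p_ann)
        paths[f"expression_{sp}"] = p_expr
        paths[f"annotations_{sp}"] = p_ann

    p_matrix = directory / "OrthologousMatrix.txt"
    p_map = directory / "Map-SeqNum-ID.txt"
    write_oma_orthologs(bundle.ortholog_map, p_matrix, p_map)
    paths["ortholog_matrix"] = p_matrix
    paths["ortholog_map"] = p_map

    first = bundle.species[0]
    sets: dict[str, list[str]] = {}
    for name, shared in bundle.truth.shared_flags.items():
        sp = first if name in bundle.truth.markers[first] else bundle.species[1]
        sets[name] = list(bundle.truth.markers[sp][name])
    gmt = GeneSetCollection(sets=sets, source="planted_markers")
    p_gmt = directory / "planted_markers.gmt"
    write_gmt(gmt, p_gmt)
    paths["gmt"] = p_gmt

    for sp in bundle.species:
        for tag, frame in (("A_true", bundle.truth.A_true[sp]),
                           ("P_true", bundle.truth.P_true[sp])):
            p = directory / f"{tag}_{sp}.tsv"
            frame.to_csv(p, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")
            paths[f"{tag}_{sp}"] = p

    sidecar = {
        "scenario": bundle.scenario.to_dict(),
        "seed": bundle.truth.seed,
        "shared_flags": bundle.truth.shared_flags,
        "markers": bundle.truth.markers,
        "depth_factors": {
            sp: {s: float(v) for s, v in series.items()}
            for sp, series in bundle.truth.depth_factors.items()
        },
        "species": bundle.species,
    }
    p_truth = directory / "truth.json"
    p_truth.write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["truth"] = p_truth
    return paths


def read_fixture_bundle(directory: str | Path) -> SyntheticBundle:
    """Read back a fixture bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "truth.json").read_text(encoding="utf-8"))
    scenario = SyntheticScenario.from_dict(sidecar["scenario"])
    species = sidecar["species"]
    datasets = {}
    for sp in species:
        expr = read_expression_tsv(directory / f"expression_{sp}.tsv")
        anns = read_sample_annotations(directory / f"annotations_{sp}.tsv")
        datasets[sp] = SyntheticDataset(species=sp, expression=expr, annotations=anns)
    omap = read_oma_orthologs(
        directory / "OrthologousMatrix.txt",
        directory / "Map-SeqNum-ID.txt",
        species[0],
        species[1],
    )
    A_true = {
        sp: pd.read_csv(directory / f"A_true_{sp}.tsv", sep="\t", index_col=0)
        for sp in species
    }
    P_true = {
        sp: pd.read_csv(directory / f"P_true_{sp}.tsv", sep="\t", index_col=0)
        for sp in species
    }
    truth = SyntheticTruth(
        A_true=A_true,
        P_true=P_true,
        markers=sidecar["markers"],
        depth_factors={
            sp: pd.Series(sidecar["depth_factors"][sp]) for sp in species
        },
        shared_flags=sidecar["shared_flags"],
        seed=int(sidecar["seed"]),
    )
    return SyntheticBundle(
        scenario=scenario, datasets=datasets, ortholog_map=omap, truth=truth
    )
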