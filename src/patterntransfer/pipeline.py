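"""End-to-end orchestration: factorize, classify, select k, project, enrich.

:func:`run_all` executes the full workflow on either a synthetic
scenario or user-supplied files, writing every intermediate table as TSV
plus a JSON manifest holding all seeds and parameters, so a run can be
reproduced from the manifest alone.  Each stage is a thin call into the
library modules; the subcommands of the CLI compose the same functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import gsea_pos, rank_genes_by_pattern
from .factorization import Factorization, scan_k, write_factorization
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
)
from .pattern_analysis import (
    Thresholds,
    classify_patterns,
    drop_technical_patterns,
    pattern_markers,
    select_pattern_count,
)
from .projection import compare_groups, project_patterns, restrict_to_orthologs
from .synthetic_data import SyntheticScenario, generate_scenario

__all__ = ["RunConfig", "run_all", "run_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized into the manifest."""

    scenario: SyntheticScenario | None = None
    datasets: list[dict] = field(default_factory=list)  # {name, expression, annotations}
    ortholog: dict | None = None  # {matrix, map, species_a, species_b}
    gmt: str | None = None
    k_min: int = 2
    k_max: int = 8
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_sets: int = 1
    n_restarts: int = 2
    max_iter: int = 2000
    tol: float = 1e-6
    center: bool = True
    equal_var: bool = True
    n_perm: int = 1000
    min_size: int = 5
    max_size: int = 500
    exponent: float = 1.0
    seed: int = 0
    outdir: str = "patterntransfer_run"

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = SyntheticScenario.from_dict(raw["scenario"])
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "scenario": None if self.scenario is None else self.scenario.to_dict(),
            "datasets": self.datasets,
            "ortholog": self.ortholog,
            "gmt": self.gmt,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "thresholds": {
                "dominance": self.thresholds.dominance,
                "eta2": self.thresholds.eta2,
                "depth": self.thresholds.depth,
            },
            "n_sets": self.n_sets,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "center": self.center,
            "equal_var": self.equal_var,
            "n_perm": self.n_perm,
            "min_size": self.min_size,
            "max_size": self.max_size,
            "exponent": self.exponent,
            "seed": self.seed,
            "outdir": self.outdir,
        }


def _write_tsv(frame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False,
                 float_format=FLOAT_FORMAT, lineterminator="\n")


def _dataset_seed(seed: int, name: str) -> int:
    h = int(np.random.SeedSequence(
        [seed, *(ord(c) for c in name)]
    ).generate_state(1)[0])
    return h


def run_dataset(
    name: str,
    expression: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    config: RunConfig,
    outdir: Path,
) -> dict:
    """Scan k, classify, select the pattern count, drop technical
    patterns and compute markers for one dataset.  Returns a summary dict
    including the retained :class:`Factorization`."""
    seed = _dataset_seed(config.seed, name)
    k_max = min(config.k_max, expression.n_genes, expression.n_samples)
    facts = scan_k(
        expression, config.k_min, k_max, seed=seed,
        n_sets=config.n_sets, max_iter=config.max_iter, tol=config.tol,
        n_restarts=config.n_restarts,
    )
    classifications = {}
    scan_rows = []
    for fact in facts:
        cls = classify_patterns(fact, annotations, config.thresholds)
        classifications[fact.k] = cls
        cats = cls.categories()
        scan_rows.append(
            {
                "k": fact.k,
                "frobenius_error": fact.frobenius_error,
                "n_sample_specific": cats.count("sample_specific"),
                "n_technical": cats.count("technical"),
                "categories": ",".join(cats),
            }
        )
    import pandas as pd

    _write_tsv(pd.DataFrame(scan_rows), outdir / "datasets" / name / "scan_summary.tsv")
    selected_k = select_pattern_count(classifications)
    fact = next(f for f in facts if f.k == selected_k)
    cls = classifications[selected_k]
    _write_tsv(cls.to_frame(), outdir / "datasets" / name / "classification.tsv")
    n_technical = cls.categories().count("technical")
    fact_final = drop_technical_patterns(fact, cls, X=expression)
    write_factorization(fact_final, outdir / "datasets" / name / "factorization")
    markers = pattern_markers(fact_final) if fact_final.k >= 2 else None
    if markers is not None:
        _write_tsv(markers.table, outdir / "datasets" / name / "markers.tsv")
    return {
        "name": name,
        "seed": seed,
        "selected_k": selected_k,
        "n_technical_dropped": n_technical,
        "factorization": fact_final,
        "classification": cls,
        "markers": markers,
    }


def _load_inputs(config: RunConfig):
    datasets: dict[str, tuple[ExpressionMatrix, list[SampleAnnotation]]] = {}
    omap: OrthologMap | None = None
    gmt: GeneSetCollection | None = None
    if config.scenario is not None:
        bundle = generate_scenario(config.scenario)
        for sp, ds in bundle.datasets.items():
            datasets[sp] = (ds.expression, ds.annotations)
        omap = bundle.ortholog_map
        gmt = GeneSetCollection(
            sets={
                name: list(bundle.truth.markers[bundle.species[0]].get(
                    name, bundle.truth.markers[bundle.species[1]].get(name, [])
                ))
                for name in bundle.truth.shared_flags
            },
            source="planted_markers",
        )
    for entry in config.datasets:
        datasets[entry["name"]] = (
            read_expression_tsv(entry["expression"]),
            read_sample_annotations(entry["annotations"]),
        )
    if config.ortholog is not None:
        omap = read_oma_orthologs(
            config.ortholog["matrix"],
            config.ortholog["map"],
            config.ortholog["species_a"],
            config.ortholog["species_b"],
        )
    if config.gmt is not None:
        gmt = read_gmt(config.gmt)
    if not datasets:
        raise ValueError("no dataset: supply a scenario or dataset paths")
    return datasets, omap, gmt


def _project_pair(
    src_name: str,
    src_fact: Factorization,
    tgt_name: str,
    tgt_expr: ExpressionMatrix,
    tgt_anns: list[SampleAnnotation],
    omap: OrthologMap | None,
    config: RunConfig,
    outdir: Path,
) -> dict:
    import pandas as pd

    A = src_fact.a_frame()
    same_namespace = set(src_fact.gene_ids) & set(tgt_expr.gene_ids)
    if omap is not None and not same_namespace:
        aligned = restrict_to_orthologs(A, tgt_expr, omap)
    else:
        # same-species projection: identity gene correspondence
        shared = [g for g in src_fact.gene_ids if g in set(tgt_expr.gene_ids)]
        identity = OrthologMap(
            species_a=src_name, species_b=tgt_name, pairs=[(g, g) for g in shared]
        )
        aligned = restrict_to_orthologs(A, tgt_expr, identity, source_species=src_name)
    result = project_patterns(aligned, center=config.center)
    states = sorted({a.state for a in tgt_anns})
    tissues = sorted({a.tissue for a in tgt_anns})
    counts: dict[tuple[str, str], int] = {}
    for a in tgt_anns:
        counts[(a.tissue, a.state)] = counts.get((a.tissue, a.state), 0) + 1
    for pattern in result.source_pattern_ids:
        for tissue in tissues:
            for i, sa in enumerate(states):
                for sb in states[i + 1:]:
                    if counts.get((tissue, sa), 0) >= 2 and counts.get((tissue, sb), 0) >= 2:
                        compare_groups(
                            result, tgt_anns, pattern, sa, sb,
                            tissue=tissue, equal_var=config.equal_var,
                        )
    pair_dir = outdir / "projection" / f"{src_name}__into__{tgt_name}"
    pair_dir.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(pair_dir / "scores.tsv", sep="\t",
                         float_format=FLOAT_FORMAT, lineterminator="\n")
    _write_tsv(result.tests_frame(), pair_dir / "group_tests.tsv")
    return {
        "source": src_name,
        "target": tgt_name,
        "n_genes_used": result.n_genes_used,
        "n_pairs_dropped": aligned.n_dropped,
        "n_group_tests": len(result.group_tests),
    }


def run_all(config: RunConfig) -> Path:
    """Execute every stage and return the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, omap, gmt = _load_inputs(config)

    summaries = {}
    for name, (expr, anns) in datasets.items():
        logger.info("factorizing dataset %s", name)
        summaries[name] = run_dataset(name, expr, anns, config, outdir)

    projections = []
    names = list(datasets)
    if len(names) >= 2:
        for src in names:
            for tgt in names:
                if src == tgt:
                    continue
                if omap is None and not (
                    set(datasets[src][0].gene_ids) & set(datasets[tgt][0].gene_ids)
                ):
                    logger.info(
                        "projection %s -> %s skipped: no ortholog map and "
                        "disjoint gene namespaces", src, tgt,
                    )
                    continue
                projections.append(
                    _project_pair(
                        src, summaries[src]["factorization"],
                        tgt, datasets[tgt][0], datasets[tgt][1],
                        omap, config, outdir,
                    )
                )
    else:
        logger.info("single dataset: projection stage skipped")

    enrichment_meta = []
    if gmt is not None:
        import pandas as pd

        gmt_genes = {g for members in gmt.sets.values() for g in members}
        for name in names:
            fact = summaries[name]["factorization"]
            # reconcile namespaces: if this dataset's genes don't overlap the
            # gene-set collection, translate through the ortholog map
            symbol_map = None
            if omap is not None and not (set(fact.gene_ids) & gmt_genes):
                if set(fact.gene_ids) & {a for a, _ in omap.pairs}:
                    symbol_map = omap.a_to_b()
                elif set(fact.gene_ids) & {b for _, b in omap.pairs}:
                    symbol_map = omap.b_to_a()
            frames = []
            for pattern in fact.pattern_ids:
                ranked = rank_genes_by_pattern(
                    fact.a_frame(), pattern, symbol_map=symbol_map
                )
                res = gsea_pos(
                    ranked, gmt,
                    n_perm=config.n_perm,
                    seed=_dataset_seed(config.seed, f"gsea:{name}:{pattern}"),
                    min_size=config.min_size, max_size=config.max_size,
                    exponent=config.exponent,
                )
                if len(res):
                    res.insert(0, "pattern", pattern)
                    frames.append(res)
            if frames:
                table = pd.concat(frames, ignore_index=True)
                _write_tsv(table, outdir / "enrichment" / f"{name}.tsv")
                enrichment_meta.append({"dataset": name, "n_rows": len(table),
                                        "n_perm": config.n_perm})

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "datasets": {
            name: {
                "seed": s["seed"],
                "selected_k": s["selected_k"],
                "n_technical_dropped": s["n_technical_dropped"],
                "final_k": s["factorization"].k,
            }
            for name, s in summaries.items()
        },
        "projections": projections,
        "enrichment": enrichment_meta,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir
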