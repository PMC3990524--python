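"""End-to-end orchestration: binarize -> thresholds -> discover -> significance
-> complement propagation -> gene mapping, with run metadata for exact
reproducibility.

All randomness derives from one master seed via spawned child generators,
one per stage, so toggling a later stage never changes an earlier one.
Re-running with the same config reproduces every output bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from logicmine import __version__
from logicmine.discovery import (
    propagate_complement,
    relationships_to_frame,
    scan_higher,
    scan_lower,
)
from logicmine.errors import FormatError, ValidationError
from logicmine.genemap import map_higher, map_lower
from logicmine.matrices import (
    binarize_detection,
    build_phenotype_profiles,
    check_phenotype_profiles,
    classify_probes,
    read_annotation,
    read_labels,
    read_matrix,
)
from logicmine.nullmodel import (
    NullConfig,
    compute_thresholds,
    fdr_higher,
    fdr_lower,
    p_values,
    recurrence,
)

log = logging.getLogger("logicmine")


@dataclass
class RunConfig:
    """Inputs, null-model settings and stage toggles for one run."""

    matrix: Path
    phenotypes: Path | None = None
    labels: Path | None = None
    phenotype_order: list[str] | None = None
    annotation: Path | None = None
    out_dir: Path = Path("logicmine_out")
    seed: int = 0
    detection: bool = False
    alpha_present: float = 0.04
    alpha_marginal: float = 0.06
    null: NullConfig = field(default_factory=NullConfig)
    run_p_values: bool = True
    run_fdr: bool = True
    run_cv: bool = False
    fdr_higher_fraction: float | None = None
    keep_types: list[str] | None = None
    max_features: int | None = None


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise ValidationError(f"missing input: {what}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} not found: {path}")
    return path


class _Stage:
    """Context manager logging a stage's wall time; failures name the stage."""

    def __init__(self, name: str, timings: dict):
        self.name = name
        self.timings = timings

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.timings[self.name] = round(dt, 3)
        if exc_type is not None:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
            if issubclass(exc_type, (ValidationError, FormatError)):
                return False  # propagate with its class (CLI exit code 2)
            raise RuntimeError(f"stage {self.name!r} failed") from exc
        log.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full workflow and write reports into ``cfg.out_dir``.

    Returns a dict with the in-memory results (thresholds, relationships,
    gene relationships, FDR values) plus the paths written.
    """
    timings: dict[str, float] = {}
    out_dir = Path(cfg.out_dir)
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(("thresholds", "p_values", "fdr", "cv", "misc"), seeds)
    }

    with _Stage("load", timings):
        m = read_matrix(_require(cfg.matrix, "binary/detection matrix"))
        if cfg.detection or not np.isin(m.to_numpy(), (0, 1)).all():
            m = binarize_detection(m, cfg.alpha_present, cfg.alpha_marginal)
        m = m.astype(np.int8)
        if cfg.phenotypes is not None:
            p = read_matrix(_require(cfg.phenotypes, "phenotype profiles")).astype(np.int8)
        else:
            pairs = read_labels(_require(cfg.labels, "label table"))
            order = cfg.phenotype_order or sorted({ph for _, ph in pairs})
            p = build_phenotype_profiles(pairs, order)
        check_phenotype_profiles(p)
        if list(p.columns) != list(m.columns):
            raise ValidationError("matrix and phenotype profiles disagree on specimens")
        annotation = None
        if cfg.annotation is not None:
            annotation = read_annotation(_require(cfg.annotation, "annotation table"))
            single, _multi, _none = classify_probes(annotation)
            keep = [f for f in m.index if f in single]
            log.info("restricting to %d single-gene probes (of %d)", len(keep), m.shape[0])
            m = m.loc[keep]

    # with two complementary phenotype rows, scan one and lift the partner
    rows = p.to_numpy().astype(np.uint8)
    complementary = p.shape[0] == 2 and bool(((rows[0] ^ rows[1]) == 1).all())
    scan_phenos = [str(p.index[0])] if complementary else [str(i) for i in p.index]

    with _Stage("thresholds", timings):
        thresholds = compute_thresholds(m, p, cfg.null, rngs["thresholds"], phenotypes=scan_phenos)
        log.info("t_lower=%.6f t_higher=%.6f", thresholds.t_lower, thresholds.t_higher)

    with _Stage("discover", timings):
        lower = scan_lower(m, p, thresholds, phenotypes=scan_phenos)
        candidates = None
        if cfg.max_features is not None:
            candidates = [str(f) for f in m.index[: cfg.max_features]]
        higher = scan_higher(
            m, p, thresholds, lower, candidate_features=candidates, phenotypes=scan_phenos
        )
        rels = lower + higher
        log.info("%d lower and %d higher relationships", len(lower), len(higher))

    fdr_l = fdr_h = None
    if cfg.run_p_values:
        with _Stage("p_values", timings):
            p_values(rels, m, p, cfg.null, rngs["p_values"])
    if cfg.run_fdr:
        with _Stage("fdr", timings):
            fdr_l = fdr_lower(
                m, p, thresholds, cfg.null, rngs["fdr"],
                actual_count=len(lower), phenotypes=scan_phenos,
            )
            fdr_h = fdr_higher(
                m, p, thresholds, cfg.null, rngs["fdr"],
                phenotypes=scan_phenos, fraction=cfg.fdr_higher_fraction,
            )
    if cfg.run_cv:
        with _Stage("recurrence", timings):
            results = recurrence(rels, m, p, cfg.null, rngs["cv"])
            kept = [r for r, res in zip(rels, results) if res.q > cfg.null.q_min]
            log.info("%d of %d relationships recur (Q > %.2f)", len(kept), len(rels), cfg.null.q_min)
            rels = kept

    with _Stage("propagate", timings):
        if complementary:
            rels = rels + propagate_complement(rels, p, m)
        if cfg.keep_types:
            from logicmine.discovery import filter_by_types

            rels = filter_by_types(rels, cfg.keep_types)

    gene_rels = None
    if annotation is not None:
        with _Stage("map_genes", timings):
            gene_rels = map_lower(
                [r for r in rels if r.logic_type.arity == 1], annotation
            ) + map_higher([r for r in rels if r.logic_type.arity == 2], annotation)

    with _Stage("write", timings):
        out_dir.mkdir(parents=True, exist_ok=True)
        rel_path = out_dir / "relationships.tsv"
        relationships_to_frame(rels).to_csv(rel_path, sep="\t", index=False)
        paths = {"relationships": str(rel_path)}
        if gene_rels is not None:
            gene_path = out_dir / "gene_relationships.tsv"
            pd.DataFrame(
                [
                    {
                        "genes": ";".join(g.gene_symbols),
                        "phenotype": g.phenotype,
                        "type_index": g.logic_type.type_index,
                        "type_name": g.logic_type.name,
                        "coefficient": g.coefficient,
                        "source_probes": ";".join(g.source_probes),
                        "type_disagreement": g.type_disagreement,
                    }
                    for g in gene_rels
                ],
                columns=[
                    "genes", "phenotype", "type_index", "type_name",
                    "coefficient", "source_probes", "type_disagreement",
                ],
            ).to_csv(gene_path, sep="\t", index=False)
            paths["gene_relationships"] = str(gene_path)
        meta = {
            "version": __version__,
            "seed": cfg.seed,
            "null_config": {
                "n_trials": cfg.null.n_trials,
                "n_threshold_trials": cfg.null.n_threshold_trials,
                "triplet_sample_fraction": cfg.null.triplet_sample_fraction,
                "n_fdr_datasets": cfg.null.n_fdr_datasets,
                "n_cv_trials": cfg.null.n_cv_trials,
                "threshold_stat": cfg.null.threshold_stat,
                "q_min": cfg.null.q_min,
            },
            "thresholds": {"t_lower": thresholds.t_lower, "t_higher": thresholds.t_higher},
            "scanned_phenotypes": scan_phenos,
            "complementary_phenotypes": complementary,
            "n_relationships": len(rels),
            "fdr_lower": fdr_l,
            "fdr_higher": fdr_h,
            "timings_s": timings,
        }
        meta_path = out_dir / "run_metadata.json"
        meta_path.write_text(json.dumps(meta, indent=2))
        paths["metadata"] = str(meta_path)

    return {
        "thresholds": thresholds,
        "relationships": rels,
        "gene_relationships": gene_rels,
        "fdr_lower": fdr_l,
        "fdr_higher": fdr_h,
        "paths": paths,
    }
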