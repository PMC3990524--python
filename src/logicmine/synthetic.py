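"""Synthetic binary datasets with planted logic relationships.

The generator emulates the structure of binarized two-phenotype microarray
detection data: a features x specimens 0/1 matrix, a complementary
two-row phenotype profile, a probe-to-gene annotation with multi-probe
genes, and a ground-truth ledger of the planted relationships.

Planted lower features are the phenotype row passed through the planted
logic function with independent flip noise.  Planted pairs are drawn so
that the composed logic vector equals the phenotype row before noise; for
the XOR/XNOR class the first member carries exactly half ones within each
phenotype class, which makes both members carry exactly zero marginal
mutual information with the phenotype — the only class for which that is
possible (for conjunctive/disjunctive classes the exact relation forces
at least one member to be strongly marginally informative, so those
plants are detectable only through their members).  Background features
are i.i.d. Bernoulli noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from logicmine.errors import ValidationError
from logicmine.logic import (
    HIGHER_FUNCTIONS,
    LOWER_FUNCTIONS,
    LogicFunction,
    apply_logic,
    function_by_name,
)


@dataclass
class PlantedRelationship:
    feature_ids: tuple[str, ...]
    phenotype: str
    type_index: int
    type_name: str
    epsilon: float

    @property
    def key(self) -> tuple[tuple[str, ...], str, int]:
        return (self.feature_ids, self.phenotype, self.type_index)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted: list[PlantedRelationship]
    gene_map: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": [asdict(p) for p in self.planted],
                "gene_map": self.gene_map,
            },
            indent=2,
        )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults: two complementary phenotypes with 60 specimens each, 2000
    background features at density 0.3, ten identity-type and ten
    negation-type lower plants with 5% flip noise, and three AND plus
    three XOR pair plants without noise.
    """

    n_per_phenotype: tuple[int, int] = (60, 60)
    phenotype_names: tuple[str, str] = ("AC", "SCC")
    n_background: int = 2000
    background_density: float = 0.3
    lower_plants: Mapping[int, int] = field(default_factory=lambda: {1: 10, 2: 10})
    lower_noise: float = 0.05
    higher_plants: Mapping[str, int] = field(default_factory=lambda: {"AND": 3, "XOR": 3})
    higher_noise: float = 0.0
    probes_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.1, 4: 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.background_density < 1.0):
            raise ValidationError("background_density must be in (0, 1)")
        for eps in (self.lower_noise, self.higher_noise):
            if not (0.0 <= eps < 0.5):
                raise ValidationError("flip noise must be in [0, 0.5)")
        if any(k < 0 for k in (*self.lower_plants.values(), *self.higher_plants.values())):
            raise ValidationError("plant counts must be non-negative")
        if min(self.n_per_phenotype) < 1:
            raise ValidationError("each phenotype needs at least one specimen")


def _flip(v: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    if eps == 0.0:
        return v.copy()
    return (v ^ (rng.random(v.size) < eps)).astype(np.uint8)


def _balanced_half(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """0/1 vector with exactly floor(half) ones inside ``mask``, zero outside."""
    idx = np.where(mask)[0]
    out = np.zeros(mask.size, dtype=np.uint8)
    take = idx.size // 2
    out[rng.choice(idx, size=take, replace=False)] = 1
    return out


def _plant_pair(
    func: LogicFunction, c: np.ndarray, eps: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (a, b) with func(a, b) == c before noise.

    XOR-class plants use the balanced construction (members marginally
    uninformative); all other classes draw each specimen's input combo
    uniformly among the combos consistent with the output bit.
    """
    n = c.size
    if func.name in ("XOR", "XNOR"):
        if min(int(c.sum()), int(n - c.sum())) < 2:
            raise ValidationError(f"{func.name} plant needs at least 2 specimens per class")
        a = (_balanced_half(c == 1, rng) | _balanced_half(c == 0, rng)).astype(np.uint8)
        b = a ^ c if func.name == "XOR" else (a ^ c ^ 1).astype(np.uint8)
    else:
        table = np.asarray(func.truth_table, dtype=np.uint8)  # f(00),f(01),f(10),f(11)
        a = np.zeros(n, dtype=np.uint8)
        b = np.zeros(n, dtype=np.uint8)
        for bit in (0, 1):
            combos = np.where(table == bit)[0]
            pos = np.where(c == bit)[0]
            chosen = rng.choice(combos, size=pos.size)
            a[pos] = (chosen >> 1) & 1
            b[pos] = chosen & 1
    return _flip(a, eps, rng), _flip(b, eps, rng)


def _assign_genes(
    segments: list[list[str]], dist: Mapping[int, float], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Group probes into genes, drawing gene sizes from ``dist``.

    Genes never span segment boundaries, so probes of one gene always
    measure the same planted signal (mirroring the observed per-gene
    consistency of lower logic types in real multi-probe genes).
    """
    sizes = np.array(sorted(dist.keys()))
    probs = np.array([dist[k] for k in sizes], dtype=float)
    probs = probs / probs.sum()
    annotation: dict[str, list[str]] = {}
    gene_no = 0
    for segment in segments:
        i = 0
        while i < len(segment):
            size = int(rng.choice(sizes, p=probs))
            gene = f"GENE{gene_no:05d}"
            gene_no += 1
            for probe in segment[i : i + size]:
                annotation[probe] = [gene]
            i += size
    return annotation


def generate(
    cfg: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], SyntheticTruth]:
    """Generate (binary matrix, phenotype profiles, annotation, truth).

    Deterministic for a fixed config/seed.  All planted relationships
    target the first phenotype; the complementary phenotype carries the
    output-negated partner relationships implicitly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1, n2 = cfg.n_per_phenotype
    n = n1 + n2
    ph1, ph2 = cfg.phenotype_names
    specimen_ids = [f"S{k:04d}" for k in range(n)]
    profiles = pd.DataFrame(
        np.vstack([np.r_[np.ones(n1), np.zeros(n2)], np.r_[np.zeros(n1), np.ones(n2)]]).astype(np.int8),
        index=[ph1, ph2],
        columns=specimen_ids,
    )
    c = profiles.loc[ph1].to_numpy().astype(np.uint8)

    rows: list[np.ndarray] = []
    ids: list[str] = []
    segments: list[list[str]] = []
    planted: list[PlantedRelationship] = []
    counter = 0

    def _pid() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:06d}_at"

    for type_index in sorted(cfg.lower_plants):
        func = LOWER_FUNCTIONS[int(type_index)]
        segment: list[str] = []
        for _ in range(cfg.lower_plants[type_index]):
            pid = _pid()
            rows.append(_flip(apply_logic(func, c), cfg.lower_noise, rng))
            ids.append(pid)
            segment.append(pid)
            planted.append(
                PlantedRelationship(
                    (pid,), ph1, func.type_index, func.name, cfg.lower_noise
                )
            )
        if segment:
            segments.append(segment)
    for name in sorted(cfg.higher_plants):
        func = function_by_name(name)
        if func.arity != 2 or func.type_index not in HIGHER_FUNCTIONS:
            raise ValidationError(f"not a higher logic function: {name}")
        for _ in range(cfg.higher_plants[name]):
            a, b = _plant_pair(func, c, cfg.higher_noise, rng)
            pa, pb = _pid(), _pid()
            rows.extend([a, b])
            ids.extend([pa, pb])
            segments.extend([[pa], [pb]])
            planted.append(
                PlantedRelationship(
                    (pa, pb), ph1, func.type_index, func.name, cfg.higher_noise
                )
            )
    if cfg.n_background:
        bg = (rng.random((cfg.n_background, n)) < cfg.background_density).astype(np.uint8)
        segment = []
        for k in range(cfg.n_background):
            rows.append(bg[k])
            ids.append(_pid())
            segment.append(ids[-1])
        segments.append(segment)
    matrix = pd.DataFrame(np.vstack(rows).astype(np.int8), index=ids, columns=specimen_ids)
    annotation = _assign_genes(segments, cfg.probes_per_gene, rng)
    truth = SyntheticTruth(planted=planted, gene_map=annotation)
    return matrix, profiles, annotation, truth
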