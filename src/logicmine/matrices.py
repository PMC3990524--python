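"""Delimited-matrix I/O, detection-call binarization and phenotype profiles.

Matrices are held as :class:`pandas.DataFrame` with feature (probe)
identifiers on the index and specimen identifiers on the columns, written
and read as tab-separated text in the style of GEO series matrices.  A
detection matrix holds either vendor detection calls (``P``/``M``/``A``
for Present/Marginal/Absent) or detection p-values in [0, 1]; binarization
turns Present into 1 and Marginal/Absent into 0, the reading being that a
probe flagged Marginal or Absent was not reliably detected.

Phenotype profiles are a phenotypes x specimens one-hot matrix: each
specimen column sums to exactly one, and with exactly two phenotypes the
two rows are bitwise complementary.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from logicmine.errors import FormatError, ValidationError

_FLAGS = {"P": 1, "M": 0, "A": 0}

#: GPL570-style multi-gene separator inside one annotation cell.
MULTI_GENE_SEPARATOR = "///"


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix: first row specimen ids, first column feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "feature ids")
    _check_unique(df.columns, "specimen ids")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_labels(path) -> list[tuple[str, str]]:
    """Read a two-column TSV (specimen_id, phenotype) preserving row order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (specimen_id, phenotype)")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _check_unique(ids, what: str) -> None:
    if len(ids) != len(set(ids)):
        counts = pd.Series(list(ids)).value_counts()
        dups = list(counts[counts > 1].index[:5])
        raise ValidationError(f"duplicate {what}: {dups}")


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize_detection(
    d: pd.DataFrame,
    alpha_present: float = 0.04,
    alpha_marginal: float = 0.06,
) -> pd.DataFrame:
    """Convert a detection-call matrix into a 0/1 presence matrix.

    Flag input: ``P`` -> 1, ``M``/``A`` -> 0.  P-value input: values below
    ``alpha_present`` -> 1, everything else (the Marginal band between the
    two cutoffs included) -> 0.  The defaults are the conventional MAS5
    detection cutoffs; both are configurable.
    """
    _check_unique(d.index, "feature ids")
    _check_unique(d.columns, "specimen ids")
    values = d.to_numpy()
    if values.dtype.kind in "fiu":
        if alpha_present >= alpha_marginal:
            raise ValidationError(
                f"alpha_present ({alpha_present}) must be < alpha_marginal ({alpha_marginal})"
            )
        arr = values.astype(np.float64)
        bad = np.argwhere(~((arr >= 0.0) & (arr <= 1.0)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"detection p-value outside [0, 1] at row {d.index[i]!r}, "
                f"column {d.columns[j]!r}: {arr[i, j]!r}"
            )
        out = (arr < alpha_present).astype(np.int8)
    else:
        flat = np.vectorize(lambda x: _FLAGS.get(str(x).strip(), -1), otypes=[np.int8])(values)
        bad = np.argwhere(flat < 0)
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"unknown detection flag at row {d.index[i]!r}, "
                f"column {d.columns[j]!r}: {values[i, j]!r} (expected P, M or A)"
            )
        out = flat
    return pd.DataFrame(out, index=d.index.copy(), columns=d.columns.copy())


def check_binary_matrix(b: pd.DataFrame) -> None:
    _check_unique(b.index, "feature ids")
    _check_unique(b.columns, "specimen ids")
    if not np.isin(b.to_numpy(), (0, 1)).all():
        raise ValidationError("binary matrix contains values outside {0, 1}")


# ---------------------------------------------------------------------------
# phenotype profiles
# ---------------------------------------------------------------------------

def build_phenotype_profiles(
    labels: Mapping[str, str] | Iterable[tuple[str, str]],
    order: Sequence[str],
) -> pd.DataFrame:
    """One-hot phenotypes x specimens matrix; row order follows ``order``.

    Every specimen must carry exactly one label drawn from ``order``;
    duplicate specimen ids and unknown labels are validation errors.
    """
    if isinstance(labels, Mapping):
        pairs = list(labels.items())
    else:
        pairs = list(labels)
    specimens = [s for s, _ in pairs]
    _check_unique(specimens, "specimen ids")
    if len(order) != len(set(order)):
        raise ValidationError("phenotype order contains duplicates")
    row_of = {ph: i for i, ph in enumerate(order)}
    values = np.zeros((len(order), len(pairs)), dtype=np.int8)
    for j, (specimen, phenotype) in enumerate(pairs):
        if phenotype not in row_of:
            raise ValidationError(
                f"specimen {specimen!r} has unknown phenotype {phenotype!r} "
                f"(expected one of {list(order)})"
            )
        values[row_of[phenotype], j] = 1
    return pd.DataFrame(values, index=list(order), columns=specimens)


def check_phenotype_profiles(p: pd.DataFrame) -> None:
    arr = p.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("phenotype profiles contain values outside {0, 1}")
    sums = arr.sum(axis=0)
    if not (sums == 1).all():
        bad = p.columns[np.where(sums != 1)[0][:5]].tolist()
        raise ValidationError(f"phenotype profile columns do not sum to 1: {bad}")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def parse_annotation(cell: object) -> list[str]:
    """Split one annotation cell into deduplicated gene symbols.

    ``"GENE1 /// GENE2"`` yields two symbols; blank or missing cells yield
    an empty list.  Surrounding whitespace is stripped.
    """
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    symbols = []
    for part in text.split(MULTI_GENE_SEPARATOR):
        sym = part.strip()
        if sym and sym not in symbols:
            symbols.append(sym)
    return symbols


def read_annotation(path) -> dict[str, list[str]]:
    """Read a probe -> gene-symbol table (TSV: probe_id, gene_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns (probe_id, gene_symbol)")
    probes = df.iloc[:, 0].tolist()
    _check_unique(probes, "probe ids in annotation")
    return {p: parse_annotation(cell) for p, cell in zip(probes, df.iloc[:, 1])}


def classify_probes(
    annotation: Mapping[str, Sequence[str]],
) -> tuple[set[str], set[str], set[str]]:
    """Partition probes into (single-gene, multi-gene, no-gene) sets.

    Downstream discovery uses only the single-gene set.
    """
    single, multi, none = set(), set(), set()
    for probe, genes in annotation.items():
        n = len(genes)
        (single if n == 1 else multi if n > 1 else none).add(probe)
    return single, multi, none


# ---------------------------------------------------------------------------
# column subsetting
# ---------------------------------------------------------------------------

def subset_columns(
    b: pd.DataFrame,
    p: pd.DataFrame,
    phenotypes: Sequence[str],
    n_per_phenotype: Mapping[str, int] | int,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly keep a fixed number of specimens per phenotype.

    Selection is uniform without replacement using the seeded ``rng``; the
    relative order of the kept columns is preserved in both matrices, and
    the returned profiles keep only the requested phenotype rows.
    """
    if list(b.columns) != list(p.columns):
        raise ValidationError("binary matrix and phenotype profiles have different specimens")
    check_phenotype_profiles(p)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(n_per_phenotype, int):
        n_per_phenotype = {ph: n_per_phenotype for ph in phenotypes}
    keep = np.zeros(b.shape[1], dtype=bool)
    for ph in phenotypes:
        if ph not in p.index:
            raise ValidationError(f"unknown phenotype {ph!r}")
        members = np.where(p.loc[ph].to_numpy() == 1)[0]
        want = n_per_phenotype[ph]
        if want > members.size:
            raise ValidationError(
                f"requested {want} specimens for phenotype {ph!r} "
                f"but only {members.size} are available"
            )
        keep[rng.choice(members, size=want, replace=False)] = True
    cols = b.columns[keep]
    return b.loc[:, cols].copy(), p.loc[list(phenotypes), cols].copy()
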