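"""Domain containers and tab-delimited readers/writers.

The package works with four kinds of objects:

* :class:`ExpressionDataset` -- one study's genes x samples expression matrix
  plus per-sample time-structure metadata,
* :class:`PriorMatrix` -- a signed genes x TFs connectivity matrix ``P``
  (entries may be +/-1 or signed motif counts),
* :class:`GoldStandard` -- a curated set of signed TF->gene edges held out for
  evaluation,
* sample metadata describing steady-state versus time-series structure.

All files are plain TSV.  Identifier matching is exact, case-sensitive string
match, and the canonical ordering of genes/TFs is lexicographic so repeated
runs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised on malformed input files or inconsistent containers."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample", "is_timeseries", "is_first_in_series",
                 "previous_sample", "delta_t"]


@dataclass
class SampleMetadata:
    """Per-sample time structure.

    ``previous_sample`` links a time-series sample to its predecessor;
    following the links must never cycle, and ``delta_t`` (in the study's
    time units, e.g. minutes) must be positive wherever a link is set.
    """

    samples: list[str]
    is_timeseries: np.ndarray          # bool (n,)
    is_first_in_series: np.ndarray     # bool (n,)
    previous_sample: list[str | None]
    delta_t: np.ndarray                # float (n,), nan where unset

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise DataError("duplicate sample identifiers in metadata")
        for arr in (self.is_timeseries, self.is_first_in_series, self.delta_t):
            if len(arr) != n:
                raise DataError("metadata column length mismatch")
        idx = {s: i for i, s in enumerate(self.samples)}
        for i, s in enumerate(self.samples):
            prev = self.previous_sample[i]
            needs_prev = self.is_timeseries[i] and not self.is_first_in_series[i]
            if needs_prev and prev is None:
                raise DataError(f"sample {s!r}: previous_sample required")
            if not needs_prev and prev is not None:
                raise DataError(f"sample {s!r}: unexpected previous_sample")
            if prev is not None:
                if prev not in idx:
                    raise DataError(f"sample {s!r}: unknown previous_sample {prev!r}")
                if not (self.delta_t[i] > 0):
                    raise DataError(f"sample {s!r}: delta_t must be > 0")
        # cycle check by link following
        for s in self.samples:
            seen = set()
            cur: str | None = s
            while cur is not None:
                if cur in seen:
                    raise DataError(f"previous_sample links cycle at {cur!r}")
                seen.add(cur)
                cur = self.previous_sample[idx[cur]]

    @classmethod
    def steady_state(cls, samples: list[str]) -> "SampleMetadata":
        n = len(samples)
        return cls(list(samples), np.zeros(n, bool), np.zeros(n, bool),
                   [None] * n, np.full(n, np.nan))

    def reordered(self, samples: list[str]) -> "SampleMetadata":
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise DataError(f"metadata missing samples: {missing}")
        order = [idx[s] for s in samples]
        return SampleMetadata(
            list(samples),
            self.is_timeseries[order].copy(),
            self.is_first_in_series[order].copy(),
            [self.previous_sample[i] for i in order],
            self.delta_t[order].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.samples,
            "is_timeseries": self.is_timeseries.astype(int),
            "is_first_in_series": self.is_first_in_series.astype(int),
            "previous_sample": [p if p is not None else "" for p in self.previous_sample],
            "delta_t": self.delta_t,
        })


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One study's genes x samples expression matrix."""

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray                 # (n_genes, n_samples) float
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"{self.dataset_id}: duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise DataError(f"{self.dataset_id}: duplicate sample identifiers")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"{self.dataset_id}: non-finite expression value at gene "
                f"{self.genes[bad[0]]!r}, sample {self.samples[bad[1]]!r}")
        if self.metadata.samples != self.samples:
            self.metadata = self.metadata.reordered(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise DataError(f"{self.dataset_id}: unknown gene {gene!r}") from None

    def restrict_genes(self, genes: list[str]) -> "ExpressionDataset":
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataError(f"{self.dataset_id}: missing genes {missing[:5]}")
        order = [idx[g] for g in genes]
        return ExpressionDataset(self.dataset_id, list(genes), list(self.samples),
                                 self.values[order], self.metadata)


# ---------------------------------------------------------------------------
# prior and gold standard
# ---------------------------------------------------------------------------

@dataclass
class PriorMatrix:
    """Signed genes x TFs connectivity.

    Entries > 0 encode known activation, < 0 repression, 0 no known
    interaction; magnitudes may carry motif counts.  All-zero rows and
    columns are preserved: a TF whose column is all zero triggers the
    expression fallback during TFA estimation.
    """

    genes: list[str]
    tfs: list[str]
    values: np.ndarray                 # (n_genes, n_tfs) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.genes), len(self.tfs)):
            raise DataError("prior matrix dimensions inconsistent with labels")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene identifiers in prior")
        if len(set(self.tfs)) != len(self.tfs):
            raise DataError("duplicate TF identifiers in prior")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite entries in prior matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tfs)

    def reindexed(self, genes: list[str], tfs: list[str]) -> "PriorMatrix":
        """Align to a new gene/TF universe; absent pairs become 0."""
        df = self.to_frame().reindex(index=genes, columns=tfs, fill_value=0.0)
        return PriorMatrix(list(genes), list(tfs), df.to_numpy(float, copy=True))

    def clipped(self) -> "PriorMatrix":
        """Signs only: entries clipped to {-1, 0, +1}."""
        return PriorMatrix(list(self.genes), list(self.tfs), np.sign(self.values))

    def edges(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return {(self.tfs[c], self.genes[r]) for r, c in zip(rows, cols)}


@dataclass
class GoldStandard:
    """Validated TF->gene interactions used only for evaluation."""

    edges: set[tuple[str, str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        pairs = [(tf, g) for tf, g, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise DataError("duplicate (tf, gene) pair in gold standard")
        for tf, g, s in self.edges:
            if s not in (-1, 1):
                raise DataError(f"gold-standard sign must be +/-1, got {s} for ({tf}, {g})")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(tf, g) for tf, g, _ in self.edges}

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _, _ in self.edges}

    @property
    def genes(self) -> set[str]:
        return {g for _, g, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty table")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric cell ({exc})") from None
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate row labels "
                        f"{list(df.index[df.index.duplicated()])[:3]}")
    if df.columns.duplicated().any():
        raise DataError(f"{path}: duplicate column labels")
    return df


def _parse_bool(x, where: str) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise DataError(f"{where}: cannot parse boolean {x!r}")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: metadata missing columns {missing_cols}")
    samples = list(df["sample"])
    prev = [p if p not in ("", "NA", "None") else None for p in df["previous_sample"]]
    delta = np.array([float(x) if x not in ("", "NA", "None") else np.nan
                      for x in df["delta_t"]])
    return SampleMetadata(
        samples,
        np.array([_parse_bool(x, path) for x in df["is_timeseries"]]),
        np.array([_parse_bool(x, path) for x in df["is_first_in_series"]]),
        prev, delta)


def read_expression(path, metadata_path=None, dataset_id: str | None = None) -> ExpressionDataset:
    """Load a genes x samples TSV (first column gene ids, header sample ids).

    If ``metadata_path`` is None all samples are treated as steady state.
    The metadata file must cover exactly the samples of the matrix.
    """
    df = _read_tsv_matrix(path)
    if df.isna().any().any():
        g = df.index[df.isna().any(axis=1)][0]
        raise DataError(f"{path}: missing expression value for gene {g!r}")
    samples = [str(c) for c in df.columns]
    if metadata_path is not None:
        md = read_metadata(metadata_path)
        extra = [s for s in md.samples if s not in set(samples)]
        if extra:
            raise DataError(f"{metadata_path}: metadata sample {extra[0]!r} "
                            f"absent from expression matrix")
        md = md.reordered(samples)
    else:
        md = SampleMetadata.steady_state(samples)
    return ExpressionDataset(dataset_id or str(path), [str(g) for g in df.index],
                             samples, df.to_numpy(float), md)


def read_prior(path) -> PriorMatrix:
    df = _read_tsv_matrix(path)
    return PriorMatrix([str(g) for g in df.index], [str(t) for t in df.columns],
                       df.to_numpy(float))


def read_gold_standard(path) -> GoldStandard:
    """Read a gold standard from a 3-column edge list or a signed matrix.

    The format is auto-detected from the header: a header starting with
    ``tf<TAB>gene`` is an edge list (optional third column ``sign``);
    anything else is parsed as a genes x TFs signed matrix.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] == ["tf", "gene"]:
        df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
        edges = set()
        for _, row in df.iterrows():
            sign = int(np.sign(float(row["sign"]))) if "sign" in df.columns else 1
            edges.add((row["tf"], row["gene"], sign if sign != 0 else 1))
        gs = GoldStandard(edges)
        if len(gs) != len(df):
            raise DataError(f"{path}: duplicate (tf, gene) pair in gold standard")
        return gs
    df = _read_tsv_matrix(path)
    edges = set()
    for r, c in zip(*np.nonzero(df.to_numpy())):
        edges.add((str(df.columns[c]), str(df.index[r]),
                   int(np.sign(df.iat[r, c]))))
    return GoldStandard(edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(dataset: ExpressionDataset, path, metadata_path=None) -> None:
    dataset.to_frame().to_csv(path, sep="\t", float_format="%.10g")
    if metadata_path is not None:
        dataset.metadata.to_frame().to_csv(metadata_path, sep="\t", index=False,
                                           float_format="%.10g")


def write_prior(prior: PriorMatrix, path) -> None:
    prior.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def write_gold_standard(gold: GoldStandard, path) -> None:
    rows = sorted(gold.edges)
    pd.DataFrame(rows, columns=["tf", "gene", "sign"]).to_csv(path, sep="\t", index=False)


def write_network(network, path) -> None:
    """Write a ranked network as TSV (tf, gene, combined_confidence, rank).

    Rows are sorted by descending confidence, ties broken lexicographically
    by (tf, gene).
    """
    df = network.to_frame()
    df = df.sort_values(["combined_confidence", "tf", "gene"],
                        ascending=[False, True, True], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_genes(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the genes present in all datasets.

    The shared genes are returned in one canonical (lexicographic) order so
    matrices are directly comparable across datasets.
    """
    if not datasets:
        raise DataError("align_genes requires at least one dataset")
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise DataError("no genes shared across datasets")
    order = sorted(common)
    return [ds.restrict_genes(order) for ds in datasets]
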