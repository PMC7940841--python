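"""Matrix / label I/O, run configuration, and the end-to-end pipeline.

Expression matrices travel as pandas DataFrames with gene identifiers
as the index and sample identifiers as columns (genes-in-rows, the
p >> n convention).  Files are delimited text, delimiter auto-detected
between tab and comma.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import kmeans_harness
from .gene_network import build_network, hub_genes, rank_genes
from .solver import PL21GPCA

__all__ = ["read_matrix", "write_matrix", "read_labels", "write_labels",
           "RunConfig", "run_pipeline"]

logger = logging.getLogger("pl21gpca")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    if not head.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a genes-by-samples matrix from delimited text.

    First row: sample identifiers; first column: gene identifiers.
    Raises descriptive errors on empty files, ragged rows, duplicate
    gene identifiers, or non-numeric cells (naming the offending
    gene/sample).
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric cell at gene {df.index[np.argmax(bad.values)]!r},"
                f" sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values present")
    return df


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a genes-by-samples DataFrame as delimited text."""
    df.to_csv(path, sep=sep, index_label="gene")


def read_labels(path) -> pd.Series:
    """Read sample labels: two-column (sample, label) or one label per line."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] >= 2:
        return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    return pd.Series(df.iloc[:, 0].values)


def write_labels(labels, path, sample_ids=None) -> None:
    labels = np.asarray(labels).ravel()
    ids = sample_ids if sample_ids is not None else range(1, len(labels) + 1)
    with open(path, "w") as fh:
        for s, l in zip(ids, labels):
            fh.write(f"{s}\t{l}\n")


_SOLVER_FIELDS = dict(
    n_components=4, p=0.5, lam=100.0, alpha=100.0, mu0=1e-2, rho=1.2,
    mu_max=1e7, k_neighbors=None, scheme="binary", sigma=None,
    v_update="with_A", max_iter=500, tol=1e-7, eps=1e-8,
)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, JSON round-trippable."""

    input: str = ""
    labels: str | None = None
    outdir: str = "pl21gpca_out"
    seed: int = 0
    transpose: bool = False
    log_transform: bool = False
    standardize: bool = False
    n_components: int = 4
    p: float = 0.5
    lam: float = 100.0
    alpha: float = 100.0
    mu0: float = 1e-2
    rho: float = 1.2
    mu_max: float = 1e7
    k_neighbors: int | None = None
    scheme: str = "binary"
    sigma: float | None = None
    v_update: str = "with_A"
    max_iter: int = 500
    tol: float = 1e-7
    eps: float = 1e-8
    n_runs: int = 50
    network_threshold: float = 0.8
    n_selected_genes: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def estimator(self) -> PL21GPCA:
        kwargs = {k: getattr(self, k) for k in _SOLVER_FIELDS}
        return PL21GPCA(random_state=self.seed, **kwargs)


def _preprocess(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    if cfg.transpose:
        df = df.T
    if cfg.log_transform:
        df = np.log2(df + 1.0)
    if cfg.standardize:
        sd = df.std(axis=1).replace(0.0, 1.0)
        df = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return df


def run_pipeline(config: RunConfig) -> Path:
    """Graph build -> fit -> clustering evaluation -> gene network.

    Writes U, V, diagnostics, the clustering report (when labels are
    given), the network edge list, module table and degree table, plus
    the resolved config and a log, into ``config.outdir``.  Any stage
    failure aborts with the stage name in the raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read_input"
    try:
        df = _preprocess(read_matrix(config.input), config)
        X = df.values  # genes x samples

        labels = None
        if config.labels is not None:
            stage = "read_labels"
            lab = read_labels(config.labels)
            if len(lab) != X.shape[1]:
                raise ValueError(
                    f"{len(lab)} labels for {X.shape[1]} samples in {config.input}"
                )
            labels = np.asarray(lab.values)

        stage = "fit"
        est = config.estimator().fit(X.T)
        U = est.components_.T
        V = est.embedding_

        stage = "write_factors"
        pd.DataFrame(U, index=df.index,
                     columns=[f"PC{j+1}" for j in range(U.shape[1])]
                     ).to_csv(outdir / "U.tsv", sep="\t", index_label="gene")
        pd.DataFrame(V, index=df.columns,
                     columns=[f"PC{j+1}" for j in range(V.shape[1])]
                     ).to_csv(outdir / "V.tsv", sep="\t", index_label="sample")
        diag = {
            "n_iter": est.n_iter_,
            "converged": bool(est.converged_),
            "objective_trace": est.objective_trace_,
            "residual_trace": est.residual_trace_,
            "config": json.loads(config.to_json()),
            "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        }
        (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))

        if labels is not None:
            stage = "evaluate"
            report = kmeans_harness(V, config.n_components, labels,
                                    n_runs=config.n_runs, seed=config.seed)
            (outdir / "clustering.json").write_text(
                json.dumps(report.to_dict(), indent=2))
            logger.info("ACC_mean=%.2f%% NMI_mean=%.2f%%",
                        report.acc_mean, report.nmi_mean)

        stage = "gene_network"
        ranking = rank_genes(U)
        l = config.n_selected_genes or min(500, X.shape[0])
        top = np.sort(ranking.top(l))
        net = build_network(X[top], gene_ids=[df.index[i] for i in top],
                            threshold=config.network_threshold)
        with open(outdir / "edges.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
            for i, j in zip(ii, jj):
                fh.write(f"{net.genes[i]}\t{net.genes[j]}\t{net.adjacency[i, j]:.6g}\n")
        with open(outdir / "modules.tsv", "w") as fh:
            fh.write("module\tgene\tdegree\n")
            for m, module in enumerate(net.modules, start=1):
                for i in module:
                    fh.write(f"{m}\t{net.genes[i]}\t{int(net.degrees[i])}\n")
        with open(outdir / "degrees.tsv", "w") as fh:
            fh.write("gene\tscore\tdegree\n")
            for local, i in enumerate(top):
                fh.write(f"{df.index[i]}\t{ranking.scores[i]:.6g}"
                         f"\t{int(net.degrees[local])}\n")
        (outdir / "hubs.json").write_text(json.dumps(hub_genes(net), indent=2))
        (outdir / "config.json").write_text(config.to_json())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
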