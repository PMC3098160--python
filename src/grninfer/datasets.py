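"""In-memory containers for expression data and their TSV serialisation.

All matrices are genes x observations with an explicit gene-name index.  The
on-disk dialect is plain TSV: genes as rows, a header row of time or
condition labels, values written with 12 significant digits so a write/read
round trip is lossless at that precision.  Replicated time courses are
written as one file per replicate with a ``_repK`` suffix plus a sidecar
JSON carrying provenance (seed, config hash).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "KnockoutPanel",
    "InterpolatedSeries",
    "read_expression_tsv",
    "write_expression_tsv",
]


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class TimeCourse:
    """Expression trajectories: genes x timepoints x replicates.

    ``values[i, t, r]`` is the expression of gene ``i`` at ``times[t]`` in
    replicate ``r``.  Times are strictly increasing and shared by replicates.
    """

    values: np.ndarray
    times: np.ndarray
    gene_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be genes x timepoints x replicates")
        if self.values.shape[0] != len(self.gene_names):
            raise ValueError("gene_names length does not match values")
        if self.values.shape[1] != self.times.size:
            raise ValueError("times length does not match values")
        if self.values.shape[2] < 1:
            raise ValueError("need at least one replicate")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        _check_finite("values", self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def write(self, prefix: str) -> list[str]:
        """Write one TSV per replicate (``<prefix>_repK.tsv``) + JSON sidecar."""
        paths = []
        labels = [f"{t:.12g}" for t in self.times]
        for r in range(self.n_replicates):
            p = f"{prefix}_rep{r + 1}.tsv"
            write_expression_tsv(p, self.values[:, :, r], self.gene_names, labels)
            paths.append(p)
        with open(prefix + ".json", "w") as fh:
            json.dump(
                {
                    "times": list(map(float, self.times)),
                    "replicates": self.n_replicates,
                    **self.meta,
                },
                fh,
                indent=1,
            )
        return paths

    @classmethod
    def read(cls, prefix: str) -> "TimeCourse":
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        times = np.asarray(meta.pop("times"), dtype=float)
        n_rep = int(meta.pop("replicates"))
        reps = []
        gene_names: list[str] = []
        for r in range(n_rep):
            vals, gene_names, _ = read_expression_tsv(f"{prefix}_rep{r + 1}.tsv")
            reps.append(vals)
        return cls(np.stack(reps, axis=2), times, gene_names, meta=meta)


@dataclass
class KnockoutPanel:
    """Mutant expression panel: genes x knockout conditions.

    ``mutant_values`` is genes x mutants (steady state) or genes x mutants x
    timepoints (time-resolved).  ``mutant_ids[k]`` names the gene deleted in
    column ``k``; the wild-type reference has the matching shape (genes, or
    genes x timepoints).  ``t_p`` is either the selected time index or the
    string ``"steady"``.
    """

    mutant_values: np.ndarray
    mutant_ids: list[str]
    wildtype_reference: np.ndarray
    gene_names: list[str]
    t_p: int | str = "steady"
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mutant_values = np.asarray(self.mutant_values, dtype=float)
        self.wildtype_reference = np.asarray(self.wildtype_reference, dtype=float)
        if len(set(self.mutant_ids)) != len(self.mutant_ids):
            raise ValueError("each mutant_id may appear at most once")
        if self.mutant_values.shape[0] != len(self.gene_names):
            raise ValueError("gene_names length does not match mutant_values")
        if self.mutant_values.shape[1] != len(self.mutant_ids):
            raise ValueError("mutant_ids length does not match mutant_values")
        unknown = set(self.mutant_ids) - set(self.gene_names)
        if unknown:
            raise ValueError(f"mutant ids not in gene list: {sorted(unknown)}")
        _check_finite("mutant_values", self.mutant_values)
        if self.is_time_resolved and self.times is None:
            raise ValueError("time-resolved panel requires times")

    @property
    def is_time_resolved(self) -> bool:
        return self.mutant_values.ndim == 3

    @property
    def n_genes(self) -> int:
        return self.mutant_values.shape[0]

    @property
    def n_mutants(self) -> int:
        return self.mutant_values.shape[1]

    @property
    def coverage(self) -> float:
        return self.n_mutants / self.n_genes

    def at_time(self, t_index: int | str) -> tuple[np.ndarray, np.ndarray]:
        """Return (mutant matrix genes x mutants, wild-type vector) at a time.

        ``t_index="steady"`` is only valid for steady-state panels.
        """
        if t_index == "steady":
            if self.is_time_resolved:
                raise ValueError("panel is time-resolved; pass a time index")
            return self.mutant_values, self.wildtype_reference
        if not self.is_time_resolved:
            raise ValueError("steady-state panel has no time axis")
        t = int(t_index)
        return self.mutant_values[:, :, t], self.wildtype_reference[:, t]


@dataclass
class InterpolatedSeries:
    """Densely interpolated single-replicate series with derivatives.

    ``values[i, t]`` and ``derivatives[i, t]`` on an equally spaced dense
    grid ``times`` spanning the original observation window.  Derivatives
    are the analytic derivative of each gene's fitted polynomial (or exact
    model derivatives when built directly from a simulator).
    """

    values: np.ndarray
    derivatives: np.ndarray
    times: np.ndarray
    gene_names: list[str]
    fit_degree: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.derivatives = np.asarray(self.derivatives, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.derivatives.shape:
            raise ValueError("values and derivatives must have the same shape")
        if self.values.shape != (len(self.gene_names), self.times.size):
            raise ValueError("shape mismatch between values, gene_names and times")
        _check_finite("values", self.values)
        _check_finite("derivatives", self.derivatives)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def write(self, prefix: str) -> None:
        labels = [f"{t:.12g}" for t in self.times]
        write_expression_tsv(prefix + "_values.tsv", self.values, self.gene_names, labels)
        write_expression_tsv(
            prefix + "_derivatives.tsv", self.derivatives, self.gene_names, labels
        )
        with open(prefix + ".json", "w") as fh:
            json.dump(
                {
                    "fit_degree": None
                    if self.fit_degree is None
                    else list(map(int, self.fit_degree)),
                    **self.meta,
                },
                fh,
                indent=1,
            )


def read_expression_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes-as-rows TSV matrix.

    Returns ``(values, gene_names, column_labels)``.  Raises a descriptive
    error (with line number) on ragged rows, duplicate gene names or
    non-numeric cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}:1: missing header row")
        labels = header.split("\t")[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(labels) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels) + 1} columns, "
                    f"got {len(parts)}"
                )
            gene = parts[0]
            if gene in genes:
                raise ValueError(f"{path}:{lineno}: duplicate gene name {gene!r}")
            try:
                row = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), genes, labels


def write_expression_tsv(
    path: str,
    values: np.ndarray,
    gene_names: list[str],
    column_labels: list[str],
    index_name: str = "gene",
) -> None:
    """Write a genes-as-rows TSV matrix with 12 significant digits."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(gene_names), len(column_labels)):
        raise ValueError("shape mismatch between values, gene_names and labels")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(index_name + "\t" + "\t".join(column_labels) + "\n")
        for g, row in zip(gene_names, values):
            fh.write(g + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def frame(values: np.ndarray, gene_names: list[str], labels: list[str]) -> pd.DataFrame:
    """Convenience DataFrame view (genes as rows)."""
    return pd.DataFrame(values, index=gene_names, columns=labels)
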