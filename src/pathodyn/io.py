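"""Shared data containers and plain-text readers/writers.

All tabular artifacts are TSV with explicit id columns (never positional
identity); gene sets travel as GMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "SubjectRecord",
    "read_connectome",
    "write_connectome",
    "read_cohort",
    "write_cohort",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "read_drug_signatures",
    "write_drug_signatures",
]


@dataclass
class Connectome:
    """Region labels plus a symmetric, nonnegative coupling matrix.

    Entries are anatomical connection densities (fraction of the regions'
    joint surface involved in the connection), so they live in [0, 1] with a
    zero diagonal.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("connectome entries must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.labels)


@dataclass
class SubjectRecord:
    """One participant: group label plus regional pathology and fALFF data."""

    subject_id: str
    group: str  # "CU" or "AD"
    abeta_suvr: np.ndarray
    tau_suvr: np.ndarray
    falff: np.ndarray | None = None
    true_thetas: tuple[float, float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.group not in ("CU", "AD"):
            raise ValueError(f"group must be 'CU' or 'AD', got {self.group!r}")
        self.abeta_suvr = np.asarray(self.abeta_suvr, dtype=float)
        self.tau_suvr = np.asarray(self.tau_suvr, dtype=float)
        if self.abeta_suvr.shape != self.tau_suvr.shape:
            raise ValueError("abeta and tau SUVR vectors must have equal length")
        if self.falff is not None:
            self.falff = np.asarray(self.falff, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.abeta_suvr.size


# ---------------------------------------------------------------------------
# TSV round-trips


def write_connectome(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.matrix, index=conn.labels, columns=conn.labels)
    df.to_csv(path, sep="\t", index_label="region")


def read_connectome(path) -> Connectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Connectome(labels=[str(c) for c in df.columns], matrix=df.to_numpy(float))


def write_cohort(records: list[SubjectRecord], labels: list[str], path) -> None:
    """Long-format cohort table: subject, group, region, abeta, tau, falff."""
    rows = []
    for rec in records:
        fal = rec.falff if rec.falff is not None else np.full(rec.n_regions, np.nan)
        for k, region in enumerate(labels):
            rows.append(
                (rec.subject_id, rec.group, region,
                 rec.abeta_suvr[k], rec.tau_suvr[k], fal[k])
            )
    pd.DataFrame(
        rows, columns=["subject", "group", "region", "abeta_suvr", "tau_suvr", "falff"]
    ).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> tuple[list[SubjectRecord], list[str]]:
    df = pd.read_csv(path, sep="\t")
    labels = list(dict.fromkeys(df["region"].astype(str)))
    records = []
    for sid, sub in df.groupby("subject", sort=False):
        sub = sub.set_index("region").loc[labels]
        fal = sub["falff"].to_numpy(float)
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                abeta_suvr=sub["abeta_suvr"].to_numpy(float),
                tau_suvr=sub["tau_suvr"].to_numpy(float),
                falff=None if np.all(np.isnan(fal)) else fal,
            )
        )
    return records, labels


def write_matrix_tsv(matrix: np.ndarray, index: list[str], columns: list[str],
                     path, index_label: str = "id") -> None:
    pd.DataFrame(matrix, index=index, columns=columns).to_csv(
        path, sep="\t", index_label=index_label
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, genes in sets.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_drug_signatures(library: dict[str, list[str]], path) -> None:
    """Long format: drug, rank (1 = most up-regulated), gene."""
    rows = [
        (drug, rank, gene)
        for drug, genes in library.items()
        for rank, gene in enumerate(genes, start=1)
    ]
    pd.DataFrame(rows, columns=["drug", "rank", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_drug_signatures(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for drug, sub in df.groupby("drug", sort=False):
        out[str(drug)] = list(sub.sort_values("rank")["gene"].astype(str))
    return out
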