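"""Reading and writing association edge lists and dense matrices.

The central object is :class:`AssociationMatrix`, a binary disease x microbe
incidence matrix built from a two-column TSV edge list.  Rows are diseases,
columns are microbes; this orientation is assumed by every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "read_association_edgelist",
    "write_association_edgelist",
    "write_score_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class AssociationMatrix:
    """Binary disease x microbe association matrix with identifier lists.

    Parameters
    ----------
    diseases : list of str
        Ordered disease identifiers (row labels), no duplicates.
    microbes : list of str
        Ordered microbe identifiers (column labels), no duplicates.
    values : ndarray of shape (n_diseases, n_microbes)
        Binary matrix; ``values[j, i] == 1`` iff disease ``j`` is known to be
        associated with microbe ``i``.
    """

    diseases: list[str]
    microbes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease identifiers")
        if len(set(self.microbes)) != len(self.microbes):
            raise ValueError("duplicate microbe identifiers")
        if self.values.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match identifier "
                f"lists ({len(self.diseases)}, {len(self.microbes)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_associations(self) -> int:
        """Number of known (value 1) associations."""
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.diseases), list(self.microbes), self.values.copy())

    def masked(self, pairs: list[tuple[int, int]]) -> "AssociationMatrix":
        """Return a copy with the given (disease_idx, microbe_idx) entries zeroed."""
        out = self.copy()
        for j, i in pairs:
            out.values[j, i] = 0.0
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.diseases, columns=self.microbes)


def read_association_edgelist(
    path,
    dialect: str = "disease-microbe",
    skip_header: bool = False,
    sort_ids: bool = False,
) -> AssociationMatrix:
    """Read a two-column TSV of (disease, microbe) pairs into a binary matrix.

    Duplicate pairs collapse to a single 1-entry.  ``#``-prefixed comment
    lines and blank lines are skipped.  Identifier order is first appearance
    in the file unless ``sort_ids`` forces lexicographic order.

    Parameters
    ----------
    dialect : {"disease-microbe", "microbe-disease"}
        Column order in the file.
    skip_header : bool
        Discard the first non-comment line.
    """
    if dialect not in ("disease-microbe", "microbe-disease"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        seen_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if skip_header and not seen_data:
                seen_data = True
                continue
            seen_data = True
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if dialect == "microbe-disease":
                a, b = b, a
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path}: no association records found")

    diseases = list(dict.fromkeys(d for d, _ in pairs))
    microbes = list(dict.fromkeys(m for _, m in pairs))
    if sort_ids:
        diseases, microbes = sorted(diseases), sorted(microbes)
    d_idx = {d: j for j, d in enumerate(diseases)}
    m_idx = {m: i for i, m in enumerate(microbes)}
    values = np.zeros((len(diseases), len(microbes)))
    for d, m in pairs:
        values[d_idx[d], m_idx[m]] = 1.0
    return AssociationMatrix(diseases, microbes, values)


def write_association_edgelist(assoc: AssociationMatrix, path) -> None:
    """Write the (disease, microbe) pairs with value 1 as a TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease_id\tmicrobe_id\n")
        rows, cols = np.nonzero(assoc.values)
        for j, i in zip(rows, cols):
            fh.write(f"{assoc.diseases[j]}\t{assoc.microbes[i]}\n")


def write_matrix_tsv(row_ids, col_ids, values, path) -> None:
    """Write a labelled dense matrix as TSV (header row of column ids, leading
    column of row ids).  Floats are written at full round-trip precision."""
    values = np.asarray(values)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match identifier lists")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(map(str, col_ids)) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    """Inverse of :func:`write_matrix_tsv`; returns (row_ids, col_ids, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float)


def write_score_matrix(scores, path) -> None:
    """Write a ScoreMatrix (or any object with diseases/microbes/values) as TSV."""
    write_matrix_tsv(scores.diseases, scores.microbes, scores.values, path)
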