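"""Per-gene allelic count tables.

The central data structure of the package: for every gene and every
reciprocal cross, the number of RNA-seq reads assignable to the maternal
and to the paternal allele.  Internally this is a pandas DataFrame indexed
by gene id with column pairs ``maternal_<cross>`` / ``paternal_<cross>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COL_RE = re.compile(r"^(maternal|paternal)_(.+)$")


@dataclass
class AllelicCounts:
    """Maternal/paternal read counts per gene and cross.

    Parameters
    ----------
    frame:
        DataFrame indexed by gene id with integer columns
        ``maternal_<cross>``, ``paternal_<cross>`` for each cross label,
        maternal before paternal.
    """

    frame: pd.DataFrame
    crosses: list[str] = field(init=False)

    def __post_init__(self) -> None:
        crosses: list[str] = []
        for col in self.frame.columns:
            m = _COL_RE.match(col)
            if m is None:
                raise ValueError(f"unrecognised count column {col!r}")
            if m.group(1) == "maternal":
                crosses.append(m.group(2))
        for c in crosses:
            for side in ("maternal", "paternal"):
                if f"{side}_{c}" not in self.frame.columns:
                    raise ValueError(f"missing column {side}_{c}")
        if not crosses:
            raise ValueError("count table has no crosses")
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.crosses = crosses

    # -- construction -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        gene_ids,
        maternal: np.ndarray,
        paternal: np.ndarray,
        crosses: list[str] | None = None,
    ) -> "AllelicCounts":
        """Build from (genes x crosses) maternal and paternal matrices."""
        maternal = np.atleast_2d(np.asarray(maternal))
        paternal = np.atleast_2d(np.asarray(paternal))
        if maternal.shape != paternal.shape:
            raise ValueError("maternal/paternal shapes differ")
        n_crosses = maternal.shape[1]
        if crosses is None:
            crosses = [str(i + 1) for i in range(n_crosses)]
        data = {}
        for j, c in enumerate(crosses):
            data[f"maternal_{c}"] = maternal[:, j]
            data[f"paternal_{c}"] = paternal[:, j]
        frame = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
        return cls(frame)

    # -- views ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def maternal(self) -> pd.DataFrame:
        return self.frame[[f"maternal_{c}" for c in self.crosses]]

    def paternal(self) -> pd.DataFrame:
        return self.frame[[f"paternal_{c}" for c in self.crosses]]

    def matrix(self) -> np.ndarray:
        """Counts as a genes x (2 * n_crosses) array, column order
        maternal_1, paternal_1, maternal_2, paternal_2, ..."""
        cols = []
        for c in self.crosses:
            cols += [f"maternal_{c}", f"paternal_{c}"]
        return self.frame[cols].to_numpy()

    def totals(self) -> pd.Series:
        """Total allelic counts per gene summed over parents and crosses."""
        return self.frame.sum(axis=1)

    def maternal_fraction(self) -> pd.Series:
        """Observed maternal read fraction pooled over crosses."""
        m = self.maternal().sum(axis=1)
        t = self.totals()
        with np.errstate(invalid="ignore"):
            return m / t

    def swap_parents(self) -> "AllelicCounts":
        """Relabel maternal<->paternal in every cross (reciprocal symmetry)."""
        mapping = {}
        for c in self.crosses:
            mapping[f"maternal_{c}"] = f"paternal_{c}"
            mapping[f"paternal_{c}"] = f"maternal_{c}"
        frame = self.frame.rename(columns=mapping)
        cols = []
        for c in self.crosses:
            cols += [f"maternal_{c}", f"paternal_{c}"]
        return AllelicCounts(frame[cols])

    def filter_min_total(self, min_total: int = 10) -> "AllelicCounts":
        """Keep genes with at least ``min_total`` allelic reads summed over
        parents and crosses (a gene with exactly ``min_total`` is kept)."""
        keep = self.totals() >= min_total
        return AllelicCounts(self.frame.loc[keep])

    def subset(self, gene_ids) -> "AllelicCounts":
        return AllelicCounts(self.frame.loc[gene_ids])

    # -- IO ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path) -> "AllelicCounts":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)
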