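"""Reading and writing Ct matrices and fitted embeddings.

The censoring/missing encoding contract: a qPCR entry is *censored*
(non-detect, right-censored in Ct space) if it is stored as a censor marker
(``"ND"``, empty cell, ...) or as a numeric value at or above the limit of
detection.  An entry is *missing* when it is absent or unparseable for
non-censoring reasons (failed chamber etc.).  Censored entries keep a
placeholder value for provenance; downstream numerics must always branch on
the masks, never on magic values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# empty cells default to *missing* (absent/failed entry); add "" to the
# censor markers for exports that store non-detects as blanks
DEFAULT_CENSOR_MARKERS = ("ND", "nd", "N/D", "999")


@dataclass
class CtMatrix:
    """Raw cells x genes Ct values with censoring/missing masks.

    Lower Ct means more expression.  ``lod`` is the per-gene detection-limit
    Ct (a scalar is broadcast).  ``housekeeping`` names the control genes
    used for per-cell normalization.
    """

    values: np.ndarray  # (N, D) float
    censored: np.ndarray  # (N, D) bool
    missing: np.ndarray  # (N, D) bool
    lod: np.ndarray  # (D,)
    gene_ids: list[str]
    cell_ids: list[str]
    housekeeping: list[str] = field(default_factory=list)
    cell_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        N, D = self.values.shape
        self.lod = np.broadcast_to(np.asarray(self.lod, dtype=float), (D,)).copy()
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.housekeeping = list(self.housekeeping)
        if len(self.gene_ids) != D or len(self.cell_ids) != N:
            raise ValueError("gene_ids/cell_ids do not match matrix shape")
        if len(set(self.gene_ids)) != D:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != N:
            raise ValueError("duplicate cell identifiers")
        if np.any(self.censored & self.missing):
            raise ValueError("censored and missing masks must be disjoint")
        missing_hk = set(self.housekeeping) - set(self.gene_ids)
        if missing_hk:
            raise ValueError(f"housekeeping genes not in gene_ids: {sorted(missing_hk)}")
        detected = ~(self.censored | self.missing)
        over = detected & (self.values >= self.lod[None, :])
        if np.any(over):
            raise ValueError(
                f"{int(over.sum())} entries are >= LOD but not flagged censored"
            )
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels)
            if len(self.cell_labels) != N:
                raise ValueError("cell_labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def hk_index(self) -> np.ndarray:
        return np.array([self.gene_ids.index(g) for g in self.housekeeping], dtype=int)


def read_ct_table(
    path,
    lod,
    housekeeping=(),
    censor_markers=DEFAULT_CENSOR_MARKERS,
    label_path=None,
    sep=None,
) -> CtMatrix:
    """Read a delimited Ct table (header = gene names, first column = cell ids).

    ``lod`` is a scalar or a ``{gene: lod}`` mapping.  Entries equal to a
    censor marker or numerically >= LOD become censored (marker-censored
    entries store the LOD as placeholder value); unparseable entries become
    missing.  A gene column that is entirely missing is a hard error.
    """
    df = pd.read_csv(path, index_col=0, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False)
    # pandas mangles duplicate header names; check the raw header line
    with open(path) as fh:
        header = fh.readline().strip()
    delim = sep
    if delim is None:
        delim = "\t" if "\t" in header else ","
    raw_genes = [c.strip() for c in header.split(delim)][1:]
    if len(set(raw_genes)) != len(raw_genes):
        raise ValueError("duplicate gene identifiers in header")
    gene_ids = [str(g).strip() for g in df.columns]
    cell_ids = [str(c).strip() for c in df.index]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell identifiers in index column")
    for g in housekeeping:
        if g not in gene_ids:
            raise ValueError(f"housekeeping gene {g!r} not found in header")
    D = len(gene_ids)
    if isinstance(lod, dict):
        lod_vec = np.array([float(lod[g]) for g in gene_ids])
    else:
        lod_vec = np.full(D, float(lod))
    markers = {str(m).strip() for m in censor_markers}

    raw = df.to_numpy(dtype=object)
    N = raw.shape[0]
    values = np.zeros((N, D))
    censored = np.zeros((N, D), dtype=bool)
    missing = np.zeros((N, D), dtype=bool)
    for i in range(N):
        for j in range(D):
            cell = str(raw[i, j]).strip()
            if cell in markers:
                censored[i, j] = True
                values[i, j] = lod_vec[j]
                continue
            try:
                v = float(cell)
            except ValueError:
                missing[i, j] = True
                values[i, j] = np.nan
                continue
            if not np.isfinite(v):
                missing[i, j] = True
                values[i, j] = np.nan
            elif v >= lod_vec[j]:
                censored[i, j] = True
                values[i, j] = v
            else:
                values[i, j] = v
    all_missing = missing.all(axis=0)
    if np.any(all_missing):
        bad = [gene_ids[j] for j in np.where(all_missing)[0]]
        raise ValueError(f"gene column(s) entirely missing: {bad}")

    cell_labels = None
    if label_path is not None:
        cell_labels = read_labels(label_path, cell_ids)
    return CtMatrix(values=values, censored=censored, missing=missing,
                    lod=lod_vec, gene_ids=gene_ids, cell_ids=cell_ids,
                    housekeeping=list(housekeeping), cell_labels=cell_labels)


def read_labels(path, cell_ids) -> np.ndarray:
    """Read a two-column (cell_id, label) file and align it to ``cell_ids``."""
    lab = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    lab.index = [str(c).strip() for c in lab.index]
    missing = [c for c in cell_ids if c not in lab.index]
    if missing:
        raise ValueError(f"labels missing for cells: {missing[:5]}")
    return lab.iloc[:, 0].loc[list(cell_ids)].to_numpy()


def write_embedding(model, path) -> None:
    """Write fitted latent coordinates as CSV (cell_id, z1..zQ[, label]).

    Floats are printed with 17 significant digits, so a read-back
    round-trips bit-for-bit.
    """
    X = np.asarray(model.X, dtype=float)
    Q = X.shape[1] if X.ndim == 2 else 0
    cols = {f"z{q + 1}": X[:, q] for q in range(Q)}
    cell_ids = getattr(model, "cell_ids", None)
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(X.shape[0])]
    df = pd.DataFrame(cols, index=pd.Index(cell_ids, name="cell_id"))
    labels = getattr(model, "cell_labels", None)
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, float_format="%.17g")


def read_embedding(path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Read back an embedding CSV; returns (coords, cell_ids, labels-or-None)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy()
        df = df.drop(columns="label")
    return df.to_numpy(dtype=float), [str(c) for c in df.index], labels
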