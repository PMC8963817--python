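"""Conjoint-triad protein features.

Each protein is encoded by (1) mapping its residues onto the seven
conjoint-triad classes (dipole moment / side-chain volume partition of the
20 amino acids), (2) scanning overlapping 3-mers of class indices into a
binary 343 x (n-2) occurrence matrix with exactly one 1 per valid column,
and (3) collapsing that sparse matrix to a fixed 343-vector via the leading
singular pair, sigma_1 * u_1.

Scaling the left singular vector by sigma_1 keeps sequence-length/energy
information; set ``scale_by_sigma=False`` for the unit-norm variant.  The
sign is fixed so the largest-magnitude entry is positive, which makes the
output deterministic.  Triads that cover an ambiguous residue produce an
all-zero column so the n-2 column count is preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: the seven amino-acid classes, in fixed row-index order
CONJOINT_GROUPS = ("AGV", "YMTS", "ILFP", "HNQW", "DE", "RK", "C")
N_GROUPS = 7
DEFAULT_K = 3
N_TRIADS = N_GROUPS ** DEFAULT_K  # 343

#: sentinel class index for ambiguous residues
AMBIGUOUS = -1

GROUP_INDEX = {aa: g for g, members in enumerate(CONJOINT_GROUPS) for aa in members}


def map_groups(record: SequenceRecord) -> np.ndarray:
    """Map a protein sequence to its per-residue class indices (0..6).

    Residues outside the 20 standard amino acids get the ``AMBIGUOUS``
    sentinel (-1).
    """
    if record.kind != "protein":
        raise ValueError(f"record {record.id!r} is not a protein")
    if len(record) == 0:
        raise ValueError(f"record {record.id!r} is empty")
    return np.array([GROUP_INDEX.get(aa, AMBIGUOUS) for aa in record.residues], dtype=np.int64)


def triad_row_index(g1: int, g2: int, g3: int) -> int:
    """0-based row of the triad with class indices (g1, g2, g3)."""
    return 49 * g1 + 7 * g2 + g3


def build_sparse_matrix(groups: np.ndarray, k: int = DEFAULT_K, record_id: str = "") -> sp.csc_matrix:
    """Binary 7^k x (n-(k-1)) triad occurrence matrix.

    Column j encodes the k-mer starting at position j; a column whose window
    covers an ambiguous residue is all-zero.
    """
    groups = np.asarray(groups, dtype=np.int64)
    n = groups.size
    if n < k:
        who = f" for record {record_id!r}" if record_id else ""
        raise ValueError(f"sequence length {n} is shorter than k={k}{who}")
    n_cols = n - (k - 1)
    windows = np.lib.stride_tricks.sliding_window_view(groups, k)
    valid = (windows >= 0).all(axis=1)
    powers = N_GROUPS ** np.arange(k - 1, -1, -1)
    rows = (windows[valid] * powers).sum(axis=1)
    cols = np.nonzero(valid)[0]
    data = np.ones(cols.size, dtype=np.int8)
    mat = sp.csc_matrix((data, (rows, cols)), shape=(N_GROUPS ** k, n_cols))
    n_skipped = n_cols - cols.size
    if n_skipped:
        logger.debug("%s: %d/%d triad columns skipped (ambiguous residues)", record_id, n_skipped, n_cols)
    return mat


def svd_reduce(matrix: sp.spmatrix, scale_by_sigma: bool = True) -> np.ndarray:
    """Collapse the triad matrix to sigma_1 * u_1 (leading singular pair).

    An all-zero matrix (every triad ambiguous) reduces to the zero vector.
    """
    n_rows = matrix.shape[0]
    if matrix.nnz == 0:
        logger.warning("all-zero triad matrix; returning zero feature vector")
        return np.zeros(n_rows)
    dense = np.asarray(matrix.todense(), dtype=np.float64)
    u, s, _ = np.linalg.svd(dense, full_matrices=False)
    vec = u[:, 0]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    if scale_by_sigma:
        vec = s[0] * vec
    return vec


def protein_feature_vector(record: SequenceRecord, k: int = DEFAULT_K,
                           scale_by_sigma: bool = True) -> np.ndarray:
    """End-to-end raw protein feature: groups -> triad matrix -> SVD vector."""
    groups = map_groups(record)
    mat = build_sparse_matrix(groups, k=k, record_id=record.id)
    return svd_reduce(mat, scale_by_sigma=scale_by_sigma)


def export_vectors_tsv(vectors: dict, path) -> None:
    """Write ``id<TAB>v1..v343`` rows for inspection."""
    path = Path(path)
    with open(path, "w") as fh:
        for pid in vectors:
            vals = "\t".join(f"{v:.10g}" for v in vectors[pid])
            fh.write(f"{pid}\t{vals}\n")
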