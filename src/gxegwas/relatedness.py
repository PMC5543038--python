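"""Pedigree numerator relationship matrix, IBS similarity and classical MDS.

The pedigree A matrix follows Henderson's recursive rules and is the
covariance structure used by every animal-model fit; IBS and its distance
are QC-side notions used for duplicate detection and population-structure
screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, Pedigree, ValidationError


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    ids: np.ndarray
    kind: str  # "pedigree-A" | "ibs-similarity" | "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("relationship matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("relationship matrix must be symmetric")

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], np.asarray(ids, dtype=object), self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by Henderson's recursion.

    Requires parents-before-offspring row order (guaranteed by the
    Pedigree invariant).  Founders get A_ii = 1; otherwise
    A_ij = (A_j,sire + A_j,dam)/2 for j already processed and
    A_ii = 1 + A_sire,dam / 2.
    """
    table = ped.table
    ids = table["id"].to_numpy()
    pos = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = table["sire"].to_numpy()
    dams = table["dam"].to_numpy()
    for i in range(n):
        s, d = sires[i], dams[i]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        if (si is not None and si >= i) or (di is not None and di >= i):
            raise ValidationError("pedigree rows are not in parents-first order")
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return RelationshipMatrix(A, ids, "pedigree-A")


def ibs_matrix(G: GenotypeMatrix) -> RelationshipMatrix:
    """Mean allele-sharing over SNPs non-missing in both individuals.

    Per SNP the share is 1 - |g_i - g_j| / 2; the plain allele-sharing
    formula, with no special weighting of het-het pairs.
    """
    if G.n_individuals < 2 or G.n_snps < 1:
        raise ValidationError("IBS needs >= 2 individuals and >= 1 SNP")
    called = G.called().astype(np.float64)
    joint = called @ called.T
    if (joint[~np.eye(len(joint), dtype=bool)] == 0).any():
        i, j = np.argwhere((joint == 0) & ~np.eye(len(joint), dtype=bool))[0]
        raise ValidationError(
            f"no jointly called SNPs for pair ({G.ids[i]!r}, {G.ids[j]!r})"
        )
    ind = [
        ((G.values == g) & (G.values != MISSING)).astype(np.float64) for g in (0, 1, 2)
    ]
    absdiff = np.zeros_like(joint)
    for u in range(3):
        for v in range(3):
            if u != v:
                absdiff += abs(u - v) * (ind[u] @ ind[v].T)
    ibs = 1.0 - absdiff / (2.0 * joint)
    ibs = 0.5 * (ibs + ibs.T)  # exact symmetry against fp noise
    np.fill_diagonal(ibs, 1.0)
    return RelationshipMatrix(ibs, G.ids, "ibs-similarity")


def distance_matrix(ibs: RelationshipMatrix) -> RelationshipMatrix:
    if ibs.kind != "ibs-similarity":
        raise ValidationError("distance is defined from an IBS matrix")
    return RelationshipMatrix(1.0 - ibs.values, ibs.ids, "distance")


def mds_outliers(
    distance: RelationshipMatrix,
    dims: int = 2,
    sd_multiplier: float = 6.0,
) -> tuple[pd.DataFrame, list]:
    """Classical metric MDS plus a robust per-axis outlier rule.

    Coordinates are the top ``dims`` eigenvectors of the double-centered
    squared-distance matrix, scaled by the square roots of their
    eigenvalues.  An individual is an outlier when, on any retained axis,
    its absolute deviation from the axis median exceeds
    ``sd_multiplier`` x (1.4826 x MAD).
    """
    if distance.kind != "distance":
        raise ValidationError("mds_outliers expects a distance matrix")
    D = distance.values
    n = len(D)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = -eigval[eigval < 0].sum()
    total = np.abs(eigval).sum()
    if total > 0 and neg_mass / total > 0.2:
        warnings.warn(
            "distance matrix is strongly non-Euclidean "
            f"(negative eigenvalue mass {neg_mass / total:.1%})",
            stacklevel=2,
        )
    top = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(top)
    frame = pd.DataFrame(
        coords, index=distance.ids, columns=[f"axis{k + 1}" for k in range(dims)]
    )
    outliers: set = set()
    for k in range(dims):
        x = coords[:, k]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            continue
        flagged = np.abs(x - med) > sd_multiplier * robust_sd
        outliers.update(distance.ids[flagged])
    return frame, sorted(outliers)
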