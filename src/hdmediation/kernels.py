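"""Centered linear kernels for the genome, transcriptome, and phenome.

Each modality is summarized as an individual-by-individual similarity matrix:
features are column-standardized, the linear (genetic-relationship-matrix
style) kernel K = Z Z' / m is formed, double-centered, and trace-normalized to
n so that kernels are on a common scale across modalities. Linear kernels keep
loadings well-defined as back-projections onto the measured variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataValidationError, HaplotypeDosages, OmicsMatrix

__all__ = ["KernelMatrix", "linear_kernel", "genome_kernel", "concat_tissues"]


@dataclass
class KernelMatrix:
    """Symmetric, double-centered, PSD similarity matrix for one modality."""

    individual_ids: list
    K: np.ndarray
    modality: str = "kernel"

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise DataValidationError("kernel shape does not match individual ids")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def validate(self, psd_tol: float = 1e-8) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise DataValidationError(f"{self.modality} kernel not symmetric")
        eigvals = np.linalg.eigvalsh(self.K)
        if eigvals.min() < -psd_tol * max(1.0, eigvals.max()):
            raise DataValidationError(
                f"{self.modality} kernel not PSD (min eigenvalue {eigvals.min():.3g})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.individual_ids, columns=self.individual_ids)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Drop constant columns, center and scale the rest to unit variance."""
    keep = np.ptp(X, axis=0) > 0
    if not keep.any():
        raise DataValidationError("all features constant; kernel would be zero")
    Z = X[:, keep] - X[:, keep].mean(axis=0)
    return Z / Z.std(axis=0)


def _center_and_normalize(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    row = K.mean(axis=0, keepdims=True)
    K = K - row - row.T + row.mean()
    K = 0.5 * (K + K.T)
    tr = np.trace(K)
    if tr <= 0:
        raise DataValidationError("kernel has non-positive trace after centering")
    return K * (n / tr)


def linear_kernel(features, modality: str = "kernel") -> KernelMatrix:
    """Linear kernel on column-standardized features, centered, trace = n."""
    if isinstance(features, OmicsMatrix):
        ids, X = features.individual_ids, features.array
        if modality == "kernel":
            modality = features.name
    else:
        raise TypeError("linear_kernel expects an OmicsMatrix; use genome_kernel for dosages")
    if X.shape[0] < 2:
        raise DataValidationError("need at least 2 individuals")
    Z = _standardize_columns(X)
    K = Z @ Z.T / Z.shape[1]
    return KernelMatrix(individual_ids=ids, K=_center_and_normalize(K), modality=modality)


def _kernel_from_array(X: np.ndarray, ids, modality: str) -> KernelMatrix:
    Z = _standardize_columns(X)
    K = Z @ Z.T / Z.shape[1]
    return KernelMatrix(individual_ids=ids, K=_center_and_normalize(K), modality=modality)


def genome_kernel(dosages: HaplotypeDosages, exclude=None) -> KernelMatrix:
    """Kernel on the unfolded founder-dosage array, optionally excluding a region.

    ``exclude`` is a (chrom, start_bp, end_bp) closed interval; markers inside
    it are dropped before the kernel is formed (used for distal kinship).
    """
    keep = np.ones(dosages.n_markers, dtype=bool)
    if exclude is not None:
        chrom, start, end = exclude
        inside = dosages.marker_indices(chrom=chrom, start_bp=start, end_bp=end)
        keep[inside] = False
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise DataValidationError("exclusion interval removes all markers")
    X = dosages.unfold(marker_idx=idx)
    return _kernel_from_array(X, dosages.individual_ids, modality="genome")


def concat_tissues(tissue_matrices) -> OmicsMatrix:
    """Feature-wise concatenation of per-tissue matrices with qualified ids.

    All matrices must share the aligned individual set. Feature ids are
    prefixed ``<tissue>:`` so the same gene measured in two tissues stays
    distinct; a clash after qualification is an error.
    """
    tissue_matrices = list(tissue_matrices)
    if not tissue_matrices:
        raise DataValidationError("no tissue matrices supplied")
    ids = tissue_matrices[0].individual_ids
    blocks, annots = [], []
    for t in tissue_matrices:
        if t.individual_ids != ids:
            raise DataValidationError(
                f"tissue {t.name!r} individuals do not match the aligned set"
            )
        block = t.values.copy()
        block.columns = [f"{t.name}:{c}" for c in block.columns]
        blocks.append(block)
        if t.feature_annotations is not None:
            a = t.feature_annotations.copy()
            a.index = [f"{t.name}:{c}" for c in a.index]
            if "tissue" not in a.columns:
                a["tissue"] = t.name
            annots.append(a)
    combined = pd.concat(blocks, axis=1)
    if combined.columns.has_duplicates:
        dup = combined.columns[combined.columns.duplicated()][0]
        raise DataValidationError(f"clashing feature id after tissue qualification: {dup!r}")
    annot = pd.concat(annots) if annots else None
    return OmicsMatrix(values=combined, name="transcriptome", feature_annotations=annot)
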