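"""Containers, readers/writers, and normalization for the three data modalities.

The analysis operates on three individual-level data modalities measured on the
same animals: founder-haplotype dosages (genome), one or more expression
matrices (transcriptome, per tissue), and a clinical-trait matrix (phenome).
This module defines the in-memory containers, validates their invariants,
aligns individuals across modalities, and provides the per-feature rank-based
inverse-normal transform and covariate residualization applied before kernel
construction.

Coordinates are 1-based base pairs; genomic windows are closed intervals.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypeDosages",
    "OmicsMatrix",
    "CovariateTable",
    "DataValidationError",
    "rank_inverse_normal",
    "normalize_features",
    "adjust_covariates",
    "align_individuals",
    "load_dataset",
    "write_dataset",
]

DOSAGE_TOL = 1e-6


class DataValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class HaplotypeDosages:
    """Founder-haplotype dosages: individuals x markers x founders.

    Each entry is the expected number of haplotypes (0..2) an individual
    carries from one founder strain at one marker; across founders the
    dosages at a marker sum to 2 (diploid). ``marker_map`` is a DataFrame
    with columns ``marker_id``, ``chrom``, ``pos_bp`` (1-based), sorted with
    strictly increasing positions within each chromosome.
    """

    individual_ids: list
    marker_map: pd.DataFrame
    dosages: np.ndarray
    founder_ids: list = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 3:
            raise DataValidationError(
                f"dosages must be 3-D (individuals x markers x founders), got shape {self.dosages.shape}"
            )
        n, m, f = self.dosages.shape
        if self.founder_ids is None:
            self.founder_ids = [chr(ord("A") + i) for i in range(f)]
        self.individual_ids = list(self.individual_ids)
        if len(self.individual_ids) != n:
            raise DataValidationError("individual_ids length does not match dosage array")
        if len(self.marker_map) != m:
            raise DataValidationError("marker_map length does not match dosage array")
        if f < 2:
            raise DataValidationError(f"need at least 2 founders, got {f}")
        self.validate()

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_founders(self) -> int:
        return self.dosages.shape[2]

    def validate(self) -> None:
        sums = self.dosages.sum(axis=2)
        bad = np.abs(sums - 2.0) > DOSAGE_TOL
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"founder dosages must sum to 2: individual "
                f"{self.individual_ids[i]!r} at marker "
                f"{self.marker_map['marker_id'].iloc[j]!r} sums to {sums[i, j]:.4g}"
            )
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                k = int(np.argmax(np.diff(pos) <= 0))
                raise DataValidationError(
                    f"marker positions must strictly increase within chromosome {chrom}"
                    f" (offending marker {grp['marker_id'].iloc[k + 1]!r})"
                )

    def marker_indices(self, chrom=None, start_bp=None, end_bp=None) -> np.ndarray:
        """Indices of markers on ``chrom`` within the closed window [start_bp, end_bp]."""
        mask = np.ones(self.n_markers, dtype=bool)
        if chrom is not None:
            mask &= (self.marker_map["chrom"].astype(str) == str(chrom)).to_numpy()
        if start_bp is not None:
            mask &= (self.marker_map["pos_bp"] >= start_bp).to_numpy()
        if end_bp is not None:
            mask &= (self.marker_map["pos_bp"] <= end_bp).to_numpy()
        return np.flatnonzero(mask)

    def subset_individuals(self, ids) -> "HaplotypeDosages":
        idx = _index_of(self.individual_ids, ids)
        return HaplotypeDosages(
            individual_ids=list(ids),
            marker_map=self.marker_map,
            dosages=self.dosages[idx],
            founder_ids=self.founder_ids,
        )

    def unfold(self, marker_idx=None) -> np.ndarray:
        """Flatten to individuals x (markers * founders), optionally restricted."""
        d = self.dosages if marker_idx is None else self.dosages[:, marker_idx, :]
        return d.reshape(d.shape[0], -1)


@dataclass
class OmicsMatrix:
    """A named individuals x features real matrix with optional annotations.

    ``feature_annotations``, when present, is indexed by feature id with
    columns among ``gene_id``, ``chrom``, ``tss_bp``, ``tissue``.
    """

    values: pd.DataFrame
    name: str = "omics"
    feature_annotations: pd.DataFrame = None

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataValidationError(f"duplicated individual id {dup!r} in {self.name}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataValidationError(f"duplicated feature id {dup!r} in {self.name}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataValidationError(f"non-finite values in {self.name}")

    @property
    def individual_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_individuals(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.loc[list(ids)],
            name=self.name,
            feature_annotations=self.feature_annotations,
        )


@dataclass
class CovariateTable:
    """Individuals x covariates design (numeric; e.g. sex coded 0/1)."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise DataValidationError("duplicated individual id in covariates")
        X = np.column_stack([np.ones(len(self.values)), self.values.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataValidationError(
                f"covariate design rank-deficient after adding intercept: "
                f"columns {list(self.values.columns)}"
            )

    @property
    def individual_ids(self) -> list:
        return list(self.values.index)

    def design(self) -> np.ndarray:
        """Design matrix with intercept prepended."""
        return np.column_stack([np.ones(len(self.values)), self.values.to_numpy(dtype=float)])

    def subset_individuals(self, ids) -> "CovariateTable":
        return CovariateTable(values=self.values.loc[list(ids)])


def _index_of(have, want):
    lookup = {v: i for i, v in enumerate(have)}
    try:
        return np.array([lookup[w] for w in want])
    except KeyError as err:
        raise DataValidationError(f"individual {err.args[0]!r} not present") from err


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - 0.5) / n).

    Ties receive average ranks. An all-constant input maps to zeros with a
    warning (a degenerate feature carries no information).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-D vector")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        warnings.warn("all-constant input to rank_inverse_normal; returning zeros")
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def normalize_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Apply the rank-based inverse-normal transform to every column."""
    X = matrix.array
    out = np.empty_like(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                out[:, j] = 0.0
            else:
                out[:, j] = rank_inverse_normal(col)
    return OmicsMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        name=matrix.name,
        feature_annotations=matrix.feature_annotations,
    )


def adjust_covariates(matrix: OmicsMatrix, covariates: CovariateTable) -> OmicsMatrix:
    """Replace each column by its least-squares residual on [1, covariates].

    Residual columns are orthogonal to every covariate column (and mean zero)
    up to numerical precision.
    """
    if list(matrix.individual_ids) != list(covariates.individual_ids):
        covariates = covariates.subset_individuals(matrix.individual_ids)
    X = covariates.design()
    Y = matrix.array
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return OmicsMatrix(
        values=pd.DataFrame(resid, index=matrix.values.index, columns=matrix.values.columns),
        name=matrix.name,
        feature_annotations=matrix.feature_annotations,
    )


def align_individuals(dosages, tissues, phenotypes, covariates=None):
    """Restrict every input to the sorted intersection of individual ids."""
    sets = [set(dosages.individual_ids)] + [set(t.individual_ids) for t in tissues]
    sets.append(set(phenotypes.individual_ids))
    if covariates is not None:
        sets.append(set(covariates.individual_ids))
    shared = set.intersection(*sets)
    if not shared:
        raise DataValidationError("no individuals shared across all inputs (empty intersection)")
    order = sorted(shared)
    dosages = dosages.subset_individuals(order)
    tissues = [t.subset_individuals(order) for t in tissues]
    phenotypes = phenotypes.subset_individuals(order)
    if covariates is not None:
        covariates = covariates.subset_individuals(order)
    return dosages, tissues, phenotypes, covariates


# ---------------------------------------------------------------------------
# Delimited-text readers and writers (TSV + JSON sidecar manifests)
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.md5()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(path: Path, **fields) -> None:
    manifest = dict(fields)
    manifest["checksum"] = _checksum(path)
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def write_dosages(dosages: HaplotypeDosages, prefix) -> None:
    """Write dosages as a long-format TSV plus a marker-map TSV."""
    prefix = Path(prefix)
    n, m, f = dosages.dosages.shape
    long = pd.DataFrame(
        {
            "individual": np.repeat(dosages.individual_ids, m * f),
            "marker_id": np.tile(np.repeat(dosages.marker_map["marker_id"].to_numpy(), f), n),
            "founder": np.tile(dosages.founder_ids, n * m),
            "dosage": dosages.dosages.reshape(-1),
        }
    )
    path = prefix.with_suffix(".dosages.tsv")
    long.to_csv(path, sep="\t", index=False, float_format="%.17g")
    _write_manifest(path, n_individuals=n, n_markers=m, n_founders=f)
    map_path = prefix.with_suffix(".markers.tsv")
    dosages.marker_map.to_csv(map_path, sep="\t", index=False)
    _write_manifest(map_path, n_markers=m)


def read_dosages(prefix) -> HaplotypeDosages:
    prefix = Path(prefix)
    marker_map = pd.read_csv(prefix.with_suffix(".markers.tsv"), sep="\t")
    if not {"marker_id", "chrom", "pos_bp"} <= set(marker_map.columns):
        raise DataValidationError(
            f"marker map {prefix.with_suffix('.markers.tsv')} must have columns "
            f"marker_id, chrom, pos_bp; got {list(marker_map.columns)}"
        )
    long = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", float_precision="round_trip")
    individuals = list(dict.fromkeys(long["individual"]))
    founders = list(dict.fromkeys(long["founder"]))
    markers = marker_map["marker_id"].to_list()
    n, m, f = len(individuals), len(markers), len(founders)
    arr = long["dosage"].to_numpy(dtype=float).reshape(n, m, f)
    return HaplotypeDosages(
        individual_ids=individuals, marker_map=marker_map, dosages=arr, founder_ids=founders
    )


def write_matrix(matrix: OmicsMatrix, path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="individual", float_format="%.17g")
    _write_manifest(
        path,
        n_individuals=len(matrix.individual_ids),
        n_features=len(matrix.feature_ids),
        name=matrix.name,
    )
    if matrix.feature_annotations is not None:
        annot_path = Path(str(path).replace(".tsv", "") + ".annotations.tsv")
        matrix.feature_annotations.to_csv(annot_path, sep="\t", index_label="feature_id")
        _write_manifest(annot_path, n_features=len(matrix.feature_annotations))


def read_matrix(path, name="omics", annotations_path=None) -> OmicsMatrix:
    values = pd.read_csv(path, sep="\t", index_col="individual", float_precision="round_trip")
    annot = None
    if annotations_path is not None and Path(annotations_path).exists():
        annot = pd.read_csv(annotations_path, sep="\t", index_col="feature_id")
    return OmicsMatrix(values=values, name=name, feature_annotations=annot)


def load_dataset(paths: dict):
    """Load a full dataset from a path descriptor and align individuals.

    ``paths`` keys: ``dosages`` (prefix for .dosages.tsv/.markers.tsv),
    ``expression`` (mapping tissue -> TSV path), ``phenotypes`` (TSV path),
    optional ``covariates`` (TSV path). All outputs are restricted to the
    intersection of individuals, in one canonical (sorted) order.
    """
    for key in ("dosages", "expression", "phenotypes"):
        if key not in paths:
            raise DataValidationError(f"path descriptor missing required key {key!r}")
    dosages = read_dosages(paths["dosages"])
    tissues = []
    for tissue, p in paths["expression"].items():
        annot = Path(str(p).replace(".tsv", "") + ".annotations.tsv")
        tissues.append(read_matrix(p, name=tissue, annotations_path=annot))
    phenotypes = read_matrix(paths["phenotypes"], name="phenotypes")
    covariates = None
    if paths.get("covariates"):
        cov_values = pd.read_csv(paths["covariates"], sep="\t", index_col="individual", float_precision="round_trip")
        covariates = CovariateTable(values=cov_values)
    return align_individuals(dosages, tissues, phenotypes, covariates)


def write_dataset(outdir, dosages, tissues, phenotypes, covariates=None) -> dict:
    """Write a dataset in the load_dataset layout; returns the path descriptor."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dosages(dosages, outdir / "genome")
    expression = {}
    for t in tissues:
        p = outdir / f"expression.{t.name}.tsv"
        write_matrix(t, p)
        expression[t.name] = p
    pheno_path = outdir / "phenotypes.tsv"
    write_matrix(phenotypes, pheno_path)
    paths = {"dosages": outdir / "genome", "expression": expression, "phenotypes": pheno_path}
    if covariates is not None:
        cov_path = outdir / "covariates.tsv"
        covariates.values.to_csv(cov_path, sep="\t", index_label="individual")
        _write_manifest(cov_path, n_individuals=len(covariates.individual_ids))
        paths["covariates"] = cov_path
    return paths
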