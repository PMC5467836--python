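"""Genotype container, SNP quality control, imputation, codings and PCA.

QC follows the standard GWAS-style pruning triplet: minor-allele frequency,
per-SNP missing fraction, and a Hardy-Weinberg equilibrium goodness-of-fit
test.  Thresholds are strict inequalities: a SNP is retained iff
``MAF > maf_min`` and ``missing fraction < miss_max`` and ``HWE p > hwe_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer
from sklearn.preprocessing import StandardScaler

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "hwe_test",
    "snp_qc",
    "impute_genotypes",
    "encode_snps",
    "genotype_pca",
    "GenotypePCA",
]

#: closed enumeration of QC failure reasons
QC_REASONS = ("ok", "maf", "missingness", "hwe")
CODINGS = ("additive", "dominant", "recessive")


@dataclass
class GenotypeMatrix:
    """Participant x SNP dosage matrix (0/1/2 minor-allele counts).

    ``dosages`` is float with NaN marking missing calls; ``key_flags`` marks
    SNPs of prior interest that enter the model explicitly (coded three ways)
    rather than being collapsed into principal components.
    """

    dosages: np.ndarray  # (n_participants, n_snps), float, NaN = missing
    snp_names: list[str]
    participants: list = field(default_factory=list)
    key_flags: np.ndarray | None = None  # bool per SNP

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[1] != len(self.snp_names):
            raise ValueError("snp_names length does not match dosage columns")
        if not self.participants:
            self.participants = [f"P{i:04d}" for i in range(self.dosages.shape[0])]
        if len(self.participants) != self.dosages.shape[0]:
            raise ValueError("participants length does not match dosage rows")
        if self.key_flags is None:
            self.key_flags = np.zeros(len(self.snp_names), dtype=bool)
        self.key_flags = np.asarray(self.key_flags, dtype=bool)
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (np.any(obs < 0) | np.any(obs > 2) | np.any(obs != np.round(obs))):
            raise ValueError("observed dosages must be integers in {0, 1, 2}")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def n_participants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing calls.

        Dosages count a designated allele; if that allele turns out to be the
        major one in-sample, the frequency is folded to the minor side.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def select_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            snp_names=[self.snp_names[i] for i in keep],
            participants=list(self.participants),
            key_flags=self.key_flags[keep],
        )

    def select_participants(self, ids) -> "GenotypeMatrix":
        idx = [self.participants.index(p) for p in ids]
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            snp_names=list(self.snp_names),
            participants=list(ids),
            key_flags=self.key_flags.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.participants, columns=self.snp_names)


@dataclass
class QCReport:
    """Per-SNP / per-participant / per-variable QC decisions with reasons."""

    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    participants: pd.DataFrame = field(default_factory=pd.DataFrame)
    variables: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        frames = []
        for section, df in (("snp", self.snps), ("participant", self.participants),
                            ("variable", self.variables)):
            if len(df):
                d = df.copy()
                d.insert(0, "section", section)
                frames.append(d)
        out = pd.concat(frames, axis=0) if frames else pd.DataFrame()
        out.to_csv(path, sep="\t", index=False)


def hwe_test(genotype_counts) -> float:
    """Hardy-Weinberg equilibrium chi-square goodness-of-fit p-value.

    Parameters
    ----------
    genotype_counts
        ``(n_AA, n_Aa, n_aa)`` observed genotype counts (hom-ref, het, hom-alt).

    Returns
    -------
    float
        1-df chi-square p-value against the HWE expectation computed from the
        sample allele frequency.  Monomorphic samples fit HWE exactly (p = 1).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa + n_ab) / (2.0 * n)  # frequency of the A allele
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    ok = expected > 0
    if not np.any(ok) or np.allclose(observed[~ok], 0):
        chi2 = float(np.sum((observed[ok] - expected[ok]) ** 2 / expected[ok]))
    else:  # observed counts in zero-expectation cells: infinitely unlikely
        return 0.0
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    obs = column[~np.isnan(column)]
    return int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2))


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Prune SNPs on MAF, missingness and Hardy-Weinberg equilibrium.

    Retains exactly the SNPs with ``MAF > maf_min`` and missing fraction
    ``< miss_max`` and HWE p-value ``> hwe_min`` (all strict).  The first
    failing criterion, in that order, is recorded as the reason.
    """
    if g.n_snps == 0 or g.n_participants == 0:
        raise ValueError("empty genotype matrix")
    maf = g.maf()
    miss = g.missing_fraction()
    hwe_p = np.empty(g.n_snps)
    for j in range(g.n_snps):
        counts = _genotype_counts(g.dosages[:, j])
        hwe_p[j] = hwe_test(counts) if sum(counts) else np.nan
    reasons = []
    for j in range(g.n_snps):
        if not maf[j] > maf_min or np.isnan(maf[j]):
            reasons.append("maf")
        elif not miss[j] < miss_max:
            reasons.append("missingness")
        elif not hwe_p[j] > hwe_min:
            reasons.append("hwe")
        else:
            reasons.append("ok")
    report = QCReport(snps=pd.DataFrame({
        "snp": g.snp_names,
        "maf": maf,
        "missing_fraction": miss,
        "hwe_p": hwe_p,
        "passed": [r == "ok" for r in reasons],
        "reason": reasons,
    }))
    kept = g.select_snps(np.array([r == "ok" for r in reasons]))
    return kept, report


def impute_genotypes(g: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Fill missing dosages by distance-weighted k-NN over participants.

    Distances are nan-Euclidean over co-observed SNPs; the weighted-mean
    dosage is rounded to the nearest integer in {0, 1, 2}.  Falls back to the
    per-SNP modal genotype when a row has no usable neighbours.  Observed
    entries are returned bit-identical.
    """
    if not np.any(g.missing_mask):
        return g
    if np.any(np.all(np.isnan(g.dosages), axis=0)):
        bad = [g.snp_names[j] for j in np.flatnonzero(np.all(np.isnan(g.dosages), axis=0))]
        raise ValueError(f"SNPs with zero observed calls cannot be imputed: {bad}")
    imputer = KNNImputer(n_neighbors=min(k, g.n_participants - 1), weights="distance")
    filled = imputer.fit_transform(g.dosages)
    if filled.shape[1] != g.n_snps:  # sklearn drops all-NaN columns; guarded above
        raise AssertionError("imputer dropped columns unexpectedly")
    filled = np.clip(np.round(filled), 0, 2)
    mask = g.missing_mask
    out = g.dosages.copy()
    out[mask] = filled[mask]
    return replace(g, dosages=out)


def encode_snps(g: GenotypeMatrix, key_snps: list[str] | None = None) -> pd.DataFrame:
    """Additive / dominant / recessive codings for the key SNPs.

    additive = dosage (0/1/2); dominant = [dosage >= 1]; recessive =
    [dosage == 2].  Column names are ``<snp>_additive`` etc.; requires a
    complete matrix for the selected SNPs.
    """
    if key_snps is None:
        key_snps = [n for n, f in zip(g.snp_names, g.key_flags) if f]
    unknown = [s for s in key_snps if s not in g.snp_names]
    if unknown:
        raise KeyError(f"unknown SNPs: {unknown}")
    cols = {}
    for snp in key_snps:
        d = g.dosages[:, g.snp_names.index(snp)]
        if np.any(np.isnan(d)):
            raise ValueError(f"SNP {snp} has missing calls; impute first")
        cols[f"{snp}_additive"] = d
        cols[f"{snp}_dominant"] = (d >= 1).astype(float)
        cols[f"{snp}_recessive"] = (d == 2).astype(float)
    return pd.DataFrame(cols, index=g.participants)


class GenotypePCA:
    """Principal components of the background (non-key) genotype matrix.

    Collapses ancestry-bearing background SNPs into a handful of orthogonal
    score columns.  SNP columns are centered and scaled before the
    decomposition; each component's sign is fixed so its largest-magnitude
    loading is positive, making scores reproducible across runs.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "GenotypePCA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "GenotypePCA":
        X = np.asarray(X, dtype=float)
        if np.any(np.isnan(X)):
            raise ValueError("genotype PCA requires a complete matrix")
        if self.n_components > min(X.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds min matrix dimension {min(X.shape)}")
        self.scaler_ = StandardScaler()
        Z = self.scaler_.fit_transform(X)
        # constant columns scale to 0; StandardScaler leaves them at 0
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full")
        self.pca_.fit(Z)
        flip = np.sign(
            self.pca_.components_[np.arange(self.n_components),
                                  np.argmax(np.abs(self.pca_.components_), axis=1)])
        flip[flip == 0] = 1.0
        self.pca_.components_ *= flip[:, None]
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.pca_.transform(Z)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def genotype_pca(g: GenotypeMatrix, n_components: int = 3) -> pd.DataFrame:
    """Participant scores on the leading genetic principal components."""
    background = g.select_snps(~g.key_flags) if np.any(g.key_flags) else g
    scores = GenotypePCA(n_components=n_components).fit_transform(background.dosages)
    return pd.DataFrame(scores, index=g.participants,
                        columns=[f"snp_pc{i + 1}" for i in range(n_components)])
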